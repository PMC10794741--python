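"""Small feed-forward regression network trained with Levenberg-Marquardt.

One hidden tanh layer (default 10 units) with a linear output, trained by
damped Gauss-Newton on the squared residuals with a light ridge penalty on
the weights, exactly the configuration classically used for small tabular
regression nets.  A held-out fold of the training rows provides early
stopping: the weights with the lowest validation error seen during training
are kept.  Training is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LMNetwork"]


def _unpack(theta: np.ndarray, p: int, h: int):
    k = 0
    w1 = theta[k : k + p * h].reshape(p, h); k += p * h
    b1 = theta[k : k + h]; k += h
    w2 = theta[k : k + h]; k += h
    b2 = theta[k]
    return w1, b1, w2, b2


@dataclass
class LMNetwork:
    """tanh(X W1 + b1) w2 + b2 fitted by Levenberg-Marquardt.

    Parameters
    ----------
    hidden : hidden-unit count.
    weight_decay : ridge coefficient on all weights (stabilizes the normal
        equations and regularizes; in FDI units² per weight²).
    max_iter : LM iteration cap.
    val_fraction : fraction of the training rows held out for early stopping.
    retries : re-initializations allowed if training diverges.
    """

    hidden: int = 10
    weight_decay: float = 1e-3
    max_iter: int = 200
    val_fraction: float = 0.15
    seed: int = 0
    retries: int = 3
    tol: float = 1e-10

    def _forward(self, X: np.ndarray, theta: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = _unpack(theta, X.shape[1], self.hidden)
        z = np.tanh(X @ w1 + b1)
        return z @ w2 + b2

    def _jacobian(self, X: np.ndarray, theta: np.ndarray):
        n, p = X.shape
        h = self.hidden
        w1, b1, w2, b2 = _unpack(theta, p, h)
        z = np.tanh(X @ w1 + b1)            # (n, h)
        yhat = z @ w2 + b2
        g = (1.0 - z**2) * w2               # (n, h): d yhat / d a_j
        J = np.empty((n, theta.size))
        J[:, : p * h] = np.einsum("np,nh->nph", X, g).reshape(n, p * h)
        J[:, p * h : p * h + h] = g
        J[:, p * h + h : p * h + 2 * h] = z
        J[:, -1] = 1.0
        return yhat, J

    def _train_once(self, X, y, rng) -> tuple[np.ndarray, float]:
        n, p = X.shape
        h = self.hidden
        n_par = p * h + 2 * h + 1

        # held-out fold for early stopping
        n_val = max(1, int(round(self.val_fraction * n))) if n >= 5 else 0
        order = rng.permutation(n)
        val_idx, fit_idx = order[:n_val], order[n_val:]
        Xf, yf = X[fit_idx], y[fit_idx]
        Xv, yv = X[val_idx], y[val_idx]

        theta = rng.normal(0.0, 1.0, n_par) / np.sqrt(max(p, 1))
        lam = self.weight_decay
        mu = 1e-2
        eye = np.eye(n_par)

        def loss(th):
            r = self._forward(Xf, th) - yf
            return float(r @ r + lam * th @ th)

        cur = loss(theta)
        best_theta = theta.copy()
        best_val = (
            float(np.mean((self._forward(Xv, theta) - yv) ** 2))
            if n_val else cur
        )
        for _ in range(self.max_iter):
            yhat, J = self._jacobian(Xf, theta)
            r = yhat - yf
            grad = J.T @ r + lam * theta
            if np.linalg.norm(grad) < self.tol:
                break
            JtJ = J.T @ J + lam * eye
            accepted = False
            while mu < 1e12:
                try:
                    step = np.linalg.solve(JtJ + mu * eye, -grad)
                except np.linalg.LinAlgError:
                    mu *= 3.0
                    continue
                cand = theta + step
                cand_loss = loss(cand)
                if np.isfinite(cand_loss) and cand_loss < cur:
                    theta, cur = cand, cand_loss
                    mu = max(mu / 3.0, 1e-12)
                    accepted = True
                    break
                mu *= 3.0
            if not accepted:
                break
            if n_val:
                val = float(np.mean((self._forward(Xv, theta) - yv) ** 2))
                if val < best_val:
                    best_val, best_theta = val, theta.copy()
            else:
                best_val, best_theta = cur, theta.copy()
        return best_theta, best_val

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LMNetwork":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n, p) with matching y")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")

        last_err: Exception | None = None
        for attempt in range(self.retries + 1):
            rng = np.random.default_rng(self.seed + 104_729 * attempt)
            try:
                theta, val = self._train_once(X, y, rng)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                last_err = exc
                continue
            if np.isfinite(val) and np.isfinite(theta).all():
                self.theta_ = theta
                self.n_features_ = X.shape[1]
                return self
        raise RuntimeError(
            f"LM training diverged after {self.retries + 1} attempts"
        ) from last_err

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_:
            raise ValueError("feature-count mismatch")
        return self._forward(X, self.theta_)
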
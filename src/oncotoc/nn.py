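"""Minimal feed-forward classifier used for every hierarchy branch.

Architecture (matching the production description): ``n_layers`` fully
connected layers, hidden width ``hidden_dim`` (default 256), batch
normalization and dropout (default rate 0.25) after every hidden affine,
ReLU activations, softmax output.  Trained with multi-class cross-entropy
via Adam (default learning rate 0.005), mini-batches, and early stopping on
a held-out validation split.

Everything is plain numpy and driven by a single ``numpy.random.Generator``,
so training is bit-reproducible for a fixed seed: same data + same seed ->
identical parameters.
"""

from __future__ import annotations

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DenseClassifier:
    """Multi-class MLP with batch norm + dropout; see module docstring."""

    def __init__(
        self,
        in_dim: int,
        n_classes: int,
        hidden_dim: int = 256,
        n_layers: int = 4,
        dropout_rate: float = 0.25,
        seed: int = 0,
    ):
        if n_layers < 2:
            raise ValueError("n_layers must be >= 2 (at least one hidden layer)")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.in_dim = in_dim
        self.n_classes = n_classes
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.dropout_rate = dropout_rate
        self.seed = seed
        self._rng = np.random.default_rng(seed)

        dims = [in_dim] + [hidden_dim] * (n_layers - 1) + [n_classes]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            # He initialization, appropriate for ReLU hidden units
            self.W.append(self._rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)))
            self.b.append(np.zeros(d_out))
        n_hidden = n_layers - 1
        self.gamma = [np.ones(hidden_dim) for _ in range(n_hidden)]
        self.beta = [np.zeros(hidden_dim) for _ in range(n_hidden)]
        self.run_mean = [np.zeros(hidden_dim) for _ in range(n_hidden)]
        self.run_var = [np.ones(hidden_dim) for _ in range(n_hidden)]

    # ---------------------------------------------------------------- forward

    def _forward_train(self, X: np.ndarray):
        cache = []
        h = X
        for l in range(self.n_layers - 1):
            z = h @ self.W[l] + self.b[l]
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            inv = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv
            self.run_mean[l] = (1 - _BN_MOMENTUM) * self.run_mean[l] + _BN_MOMENTUM * mu
            self.run_var[l] = (1 - _BN_MOMENTUM) * self.run_var[l] + _BN_MOMENTUM * var
            a = self.gamma[l] * zhat + self.beta[l]
            relu_mask = a > 0
            a = a * relu_mask
            if self.dropout_rate > 0:
                drop = (
                    self._rng.random(a.shape) >= self.dropout_rate
                ) / (1.0 - self.dropout_rate)  # inverted dropout
            else:
                drop = np.ones_like(a)
            cache.append((h, zhat, inv, relu_mask, drop))
            h = a * drop
        logits = h @ self.W[-1] + self.b[-1]
        cache.append(h)
        return logits, cache

    def _forward_eval(self, X: np.ndarray) -> np.ndarray:
        h = X
        for l in range(self.n_layers - 1):
            z = h @ self.W[l] + self.b[l]
            zhat = (z - self.run_mean[l]) / np.sqrt(self.run_var[l] + _BN_EPS)
            h = np.maximum(self.gamma[l] * zhat + self.beta[l], 0.0)
        return h @ self.W[-1] + self.b[-1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities in inference mode (dropout off, running BN
        statistics); rows are nonnegative and sum to 1."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.in_dim:
            raise ValueError(f"expected {self.in_dim} features, got {X.shape[1]}")
        return softmax(self._forward_eval(X))

    # --------------------------------------------------------------- backward

    def _backward(self, cache, probs, y_onehot, weights):
        n = probs.shape[0]
        grads_W = [None] * self.n_layers
        grads_b = [None] * self.n_layers
        grads_g = [None] * (self.n_layers - 1)
        grads_be = [None] * (self.n_layers - 1)

        h_last = cache[-1]
        dlogits = (probs - y_onehot) * weights[:, None] / weights.sum()
        grads_W[-1] = h_last.T @ dlogits
        grads_b[-1] = dlogits.sum(axis=0)
        dh = dlogits @ self.W[-1].T

        for l in range(self.n_layers - 2, -1, -1):
            h_in, zhat, inv, relu_mask, drop = cache[l]
            da = dh * drop * relu_mask
            grads_g[l] = (da * zhat).sum(axis=0)
            grads_be[l] = da.sum(axis=0)
            dzhat = da * self.gamma[l]
            m = da.shape[0]
            dz = (inv / m) * (
                m * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0)
            )
            grads_W[l] = h_in.T @ dz
            grads_b[l] = dz.sum(axis=0)
            dh = dz @ self.W[l].T
        return grads_W, grads_b, grads_g, grads_be

    # -------------------------------------------------------------------- fit

    def _params(self):
        return self.W + self.b + self.gamma + self.beta

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        learning_rate: float = 0.005,
        epochs: int = 100,
        batch_size: int = 256,
        val_fraction: float = 0.1,
        early_stop_patience: int = 10,
        class_weight: np.ndarray | None = None,
    ) -> "DenseClassifier":
        """Minimize cross-entropy with Adam.

        A ``val_fraction`` split (seeded permutation) drives early stopping
        when the data are large enough (>= 10 samples and both splits
        non-empty); the parameters with the best validation loss are kept.
        ``class_weight``: optional per-class loss weights (default uniform).
        """
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if X.shape[0] == 0:
            raise ValueError("empty training data")
        if len(np.unique(y)) < 2:
            raise ValueError(
                "only one class present in training data; degenerate branch "
                "should be handled as a pass-through, not trained"
            )
        n = X.shape[0]
        onehot = np.eye(self.n_classes)[y]
        cw = np.ones(self.n_classes) if class_weight is None else np.asarray(class_weight, float)
        sample_w = cw[y]

        perm = self._rng.permutation(n)
        n_val = int(round(n * val_fraction)) if n >= 10 else 0
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        use_val = n_val > 0 and len(tr_idx) > 0 and len(np.unique(y[tr_idx])) >= 2
        if not use_val:
            tr_idx = perm

        params = self._params()
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        t = 0
        best_loss = np.inf
        best_state = None
        stale = 0
        b1, b2, eps = 0.9, 0.999, 1e-8

        for _epoch in range(epochs):
            order = self._rng.permutation(len(tr_idx))
            for start in range(0, len(order), batch_size):
                idx = tr_idx[order[start : start + batch_size]]
                if len(idx) < 2:
                    continue  # batch norm needs >= 2 rows
                logits, cache = self._forward_train(X[idx])
                probs = softmax(logits)
                gW, gb, gg, gbe = self._backward(cache, probs, onehot[idx], sample_w[idx])
                grads = gW + gb + gg + gbe
                t += 1
                for p, g, m_, v_ in zip(params, grads, m_t, v_t):
                    m_ *= b1
                    m_ += (1 - b1) * g
                    v_ *= b2
                    v_ += (1 - b2) * g * g
                    p -= learning_rate * (m_ / (1 - b1**t)) / (
                        np.sqrt(v_ / (1 - b2**t)) + eps
                    )
            if use_val:
                probs = self.predict_proba(X[val_idx])
                loss = -np.mean(
                    sample_w[val_idx]
                    * np.log(probs[np.arange(len(val_idx)), y[val_idx]] + 1e-12)
                )
                if loss < best_loss - 1e-6:
                    best_loss = loss
                    best_state = self.get_params()
                    stale = 0
                else:
                    stale += 1
                    if stale >= early_stop_patience:
                        break
        if best_state is not None:
            self.set_params(best_state)
        return self

    # ---------------------------------------------------------------- persist

    def get_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for l in range(self.n_layers):
            out[f"W{l}"] = self.W[l].copy()
            out[f"b{l}"] = self.b[l].copy()
        for l in range(self.n_layers - 1):
            out[f"gamma{l}"] = self.gamma[l].copy()
            out[f"beta{l}"] = self.beta[l].copy()
            out[f"run_mean{l}"] = self.run_mean[l].copy()
            out[f"run_var{l}"] = self.run_var[l].copy()
        return out

    def set_params(self, state: dict[str, np.ndarray]) -> None:
        for l in range(self.n_layers):
            self.W[l] = state[f"W{l}"].copy()
            self.b[l] = state[f"b{l}"].copy()
        for l in range(self.n_layers - 1):
            self.gamma[l] = state[f"gamma{l}"].copy()
            self.beta[l] = state[f"beta{l}"].copy()
            self.run_mean[l] = state[f"run_mean{l}"].copy()
            self.run_var[l] = state[f"run_var{l}"].copy()
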
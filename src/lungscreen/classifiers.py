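"""Classification heads applied to selected feature vectors.

Three heads share one contract (``fit`` / ``predict`` / ``predict_proba``):

* :class:`Cnn1d` — a small convolutional network reading the selected
  feature vector as a 1-D signal: three convolutional layers (kernel 2,
  stride 1, ReLU) with 256, 128, and 64 filters, average pooling (size 2,
  stride 2) after the first and second, then a fully connected softmax layer
  with one unit per class.  Implemented in numpy (im2col + matmul) with an
  adaptive-moment optimizer and softmax cross-entropy.
* :class:`LdaModel` — Gaussian-Bayes linear discriminant with per-class
  means m_z = (1/n_z) sum x_i and a pooled within-class variance
  v^2 = 1/(n - c) sum (x_i - m_{z(i)})^2 shared across classes (extended
  per-feature as a diagonal covariance; the scalar form is recovered at
  d = 1).  Priors are the empirical class frequencies.
* :class:`SvmModel` — soft-margin SVM with the Gaussian RBF kernel
  exp(-gamma * ||x1 - x2||^2), one-vs-one multiclass with majority vote;
  "auto scaling" resolves gamma to 1 / (d * Var(X)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import ContractViolationError, ValidationError

# ---------------------------------------------------------------------------
# shared helpers


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def rbf_kernel(X1: np.ndarray, X2: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian RBF kernel matrix exp(-gamma * ||x1 - x2||^2)."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    sq1 = (X1 ** 2).sum(axis=1)[:, None]
    sq2 = (X2 ** 2).sum(axis=1)[None, :]
    D = np.maximum(sq1 + sq2 - 2.0 * X1 @ X2.T, 0.0)
    return np.exp(-gamma * D)


def _check_dim(expected: int, X: np.ndarray, who: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != expected:
        actual = X.shape[1] if X.ndim == 2 else X.shape
        raise ContractViolationError(
            f"{who} expects {expected} features, got {actual}")
    return X


# ---------------------------------------------------------------------------
# CNN head


@dataclass
class CnnSpec:
    """Architecture and training settings for the 1-D CNN head."""

    conv_filters: tuple[int, ...] = (256, 128, 64)
    kernel_size: int = 2
    stride: int = 1
    pool_after: tuple[int, ...] = (1, 2)   # 1-based conv layer indices
    pool_size: int = 2
    n_classes: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 8
    tol: float = 1e-5
    loss_floor: float = 1e-2   # stop once training cross-entropy is this low
    seed: int = 0


def cnn_shape_chain(d: int, spec: CnnSpec) -> list[tuple[int, int]]:
    """Symbolic (length, channels) chain through the conv/pool layers.

    'valid' convolutions shrink the length by ``kernel_size - 1`` per stride-1
    layer; each pool floors the length by ``pool_size``.
    """
    shapes = [(d, 1)]
    length, _ = shapes[-1]
    for li, filters in enumerate(spec.conv_filters, start=1):
        length = (length - spec.kernel_size) // spec.stride + 1
        if length < 1:
            raise ValidationError(
                f"feature vector too short for conv layer {li} (length {length})")
        shapes.append((length, filters))
        if li in spec.pool_after:
            length = length // spec.pool_size
            if length < 1:
                raise ValidationError(f"pool after conv {li} empties the signal")
            shapes.append((length, filters))
    return shapes


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L-k+1, k*C) sliding windows for stride-1 conv."""
    B, L, C = x.shape
    cols = [x[:, i:L - k + 1 + i, :] for i in range(k)]
    return np.concatenate(cols, axis=2)


class Cnn1d:
    """Numpy 1-D CNN over feature vectors (see module docstring).

    Inputs are standardized with training-set statistics; weights use
    seeded He initialization; optimization is adaptive-moment gradient
    descent on softmax cross-entropy with early stopping on the training
    loss plateau (or a validation set when given).
    """

    def __init__(self, spec: CnnSpec | None = None):
        self.spec = spec or CnnSpec()
        self.classes_: np.ndarray | None = None
        self.n_features_: int | None = None
        self.history_: dict = {}

    # -- parameter setup -------------------------------------------------

    def _init_params(self, d: int) -> None:
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        self.params: dict[str, np.ndarray] = {}
        chain = cnn_shape_chain(d, spec)
        c_in = 1
        # float32 throughout: halves the matmul cost at no accuracy cost for
        # a 3-layer net trained with cross-entropy
        for li, filters in enumerate(spec.conv_filters, start=1):
            fan_in = spec.kernel_size * c_in
            self.params[f"W{li}"] = (rng.standard_normal(
                (fan_in, filters)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
            self.params[f"b{li}"] = np.zeros(filters, dtype=np.float32)
            c_in = filters
        flat = chain[-1][0] * chain[-1][1]
        self.params["Wfc"] = (rng.standard_normal(
            (flat, spec.n_classes)) * np.sqrt(2.0 / flat)).astype(np.float32)
        self.params["bfc"] = np.zeros(spec.n_classes, dtype=np.float32)
        self._chain = chain

    # -- forward / backward ----------------------------------------------

    def _forward(self, X: np.ndarray, cache: bool = False):
        spec = self.spec
        a = X[:, :, None]                      # (B, d, 1)
        caches = []
        for li in range(1, len(spec.conv_filters) + 1):
            cols = _im2col(a, spec.kernel_size)
            z = cols @ self.params[f"W{li}"] + self.params[f"b{li}"]
            relu_mask = z > 0
            a_out = z * relu_mask
            pooled = li in spec.pool_after
            if pooled:
                B, L, C = a_out.shape
                Lp = L // spec.pool_size
                a_next = a_out[:, :Lp * spec.pool_size, :].reshape(
                    B, Lp, spec.pool_size, C).mean(axis=2)
            else:
                a_next = a_out
            if cache:
                caches.append((cols, relu_mask, a_out.shape, pooled))
            a = a_next
        B = a.shape[0]
        flat = a.reshape(B, -1)
        logits = flat @ self.params["Wfc"] + self.params["bfc"]
        if cache:
            return logits, flat, caches
        return logits

    def _backward(self, X, y_onehot, logits, flat, caches):
        spec = self.spec
        B = X.shape[0]
        grads: dict[str, np.ndarray] = {}
        probs = softmax(logits)
        dlogits = (probs - y_onehot) / B
        grads["Wfc"] = flat.T @ dlogits
        grads["bfc"] = dlogits.sum(axis=0)
        da_flat = dlogits @ self.params["Wfc"].T
        # un-flatten to the last activation shape
        last_len, last_ch = self._chain[-1]
        da = da_flat.reshape(B, last_len, last_ch)
        for li in range(len(spec.conv_filters), 0, -1):
            cols, relu_mask, pre_pool_shape, pooled = caches[li - 1]
            if pooled:
                Bp, L, C = pre_pool_shape
                Lp = L // spec.pool_size
                up = np.repeat(da, spec.pool_size, axis=1) / spec.pool_size
                da_out = np.zeros(pre_pool_shape, dtype=np.float32)
                da_out[:, :Lp * spec.pool_size, :] = up
            else:
                da_out = da
            dz = da_out * relu_mask
            grads[f"W{li}"] = np.tensordot(cols, dz, axes=([0, 1], [0, 1]))
            grads[f"b{li}"] = dz.sum(axis=(0, 1))
            dcols = dz @ self.params[f"W{li}"].T
            # fold the im2col windows back onto the input activation
            k = spec.kernel_size
            Bc, Lout, _ = dcols.shape
            c_in = cols.shape[2] // k
            da = np.zeros((Bc, Lout + k - 1, c_in), dtype=np.float32)
            for i in range(k):
                da[:, i:Lout + i, :] += dcols[:, :, i * c_in:(i + 1) * c_in]
        return grads

    # -- training ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None, y_val: np.ndarray | None = None
            ) -> "Cnn1d":
        spec = self.spec
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] < 8:
            raise ValidationError("CNN head needs at least 8 features")
        self.classes_ = np.unique(y)
        if self.classes_.size != spec.n_classes:
            self.spec = spec = CnnSpec(**{**spec.__dict__,
                                          "n_classes": self.classes_.size})
        self.n_features_ = X.shape[1]
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xs = ((X - self._mu) / self._sd).astype(np.float32)
        y_idx = np.searchsorted(self.classes_, y)
        Y = np.eye(spec.n_classes, dtype=np.float32)[y_idx]
        self._init_params(X.shape[1])
        rng = np.random.default_rng(spec.seed + 1)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = X.shape[0]
        best_loss = np.inf
        stall = 0
        losses: list[float] = []
        for epoch in range(spec.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, spec.batch_size):
                idx = order[start:start + spec.batch_size]
                logits, flat, caches = self._forward(Xs[idx], cache=True)
                probs = softmax(logits)
                loss = -np.mean(np.log(np.clip(
                    probs[np.arange(idx.size), y_idx[idx]], 1e-12, None)))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        f"learning rate {spec.learning_rate} likely too high")
                epoch_loss += loss * idx.size
                grads = self._backward(Xs[idx], Y[idx], logits, flat, caches)
                t += 1
                for key, g in grads.items():
                    m[key] = beta1 * m[key] + (1 - beta1) * g
                    v[key] = beta2 * v[key] + (1 - beta2) * g * g
                    mhat = m[key] / (1 - beta1 ** t)
                    vhat = v[key] / (1 - beta2 ** t)
                    self.params[key] -= spec.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss /= n
            losses.append(epoch_loss)
            monitor = epoch_loss
            if X_val is not None and y_val is not None:
                monitor = self._loss_on(X_val, y_val)
            if monitor < best_loss - spec.tol:
                best_loss = monitor
                stall = 0
            else:
                stall += 1
            if stall >= spec.patience or epoch_loss < spec.loss_floor:
                break
        self.history_ = {"train_loss": losses, "epochs_run": len(losses)}
        return self

    def _loss_on(self, X, y) -> float:
        probs = self.predict_proba(X)
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        return float(-np.mean(np.log(np.clip(
            probs[np.arange(len(y_idx)), y_idx], 1e-12, None))))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = _check_dim(self.n_features_, X, "Cnn1d")
        Xs = ((X - self._mu) / self._sd).astype(np.float32)
        out = []
        for start in range(0, X.shape[0], 512):
            out.append(softmax(self._forward(Xs[start:start + 512])))
        return np.vstack(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_cnn(X: np.ndarray, y: np.ndarray, spec: CnnSpec | None = None,
              X_val: np.ndarray | None = None, y_val: np.ndarray | None = None
              ) -> Cnn1d:
    """Fit the 1-D CNN head on a feature matrix."""
    return Cnn1d(spec).fit(X, y, X_val=X_val, y_val=y_val)


# ---------------------------------------------------------------------------
# LDA head


@dataclass
class LdaModel:
    """Pooled-variance Gaussian-Bayes discriminant (see module docstring)."""

    classes_: np.ndarray = field(default=None)
    class_means: np.ndarray = field(default=None)     # (c, d)
    pooled_variance: np.ndarray = field(default=None)  # (d,)
    priors: np.ndarray = field(default=None)
    n_features_: int = 0

    def _log_posterior(self, X: np.ndarray) -> np.ndarray:
        X = _check_dim(self.n_features_, X, "LdaModel")
        ll = np.empty((X.shape[0], self.classes_.size))
        for zi in range(self.classes_.size):
            diff = X - self.class_means[zi]
            ll[:, zi] = -0.5 * np.sum(diff ** 2 / self.pooled_variance, axis=1) \
                + np.log(self.priors[zi])
        return ll

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self._log_posterior(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._log_posterior(X), axis=1)]


def train_lda(X: np.ndarray, y: np.ndarray,
              priors: np.ndarray | None = None) -> LdaModel:
    """Fit per-class means and the pooled within-class variance.

    ``m_z = (1/n_z) sum_{i in z} x_i`` and
    ``v^2 = 1/(n - c) sum_i (x_i - m_{z(i)})^2`` per feature.  A feature with
    zero pooled variance is floored at 1e-12 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValidationError("LDA needs >= 2 samples in every class")
    n, d = X.shape
    c = classes.size
    means = np.vstack([X[y == z].mean(axis=0) for z in classes])
    resid_sq = np.zeros(d)
    for zi, z in enumerate(classes):
        diff = X[y == z] - means[zi]
        resid_sq += (diff ** 2).sum(axis=0)
    pooled = resid_sq / (n - c)
    if (pooled <= 0).any():
        warnings.warn("zero pooled variance in some features; flooring at 1e-12",
                      RuntimeWarning)
        pooled = np.maximum(pooled, 1e-12)
    if priors is None:
        priors = counts / n
    priors = np.asarray(priors, dtype=float)
    priors = priors / priors.sum()
    return LdaModel(classes_=classes, class_means=means, pooled_variance=pooled,
                    priors=priors, n_features_=d)


# ---------------------------------------------------------------------------
# SVM head


@dataclass
class SvmModel:
    """One-vs-one soft-margin SVM with linear or Gaussian RBF kernel."""

    estimator: SVC = None
    kernel: str = "rbf"
    gamma_resolved: float | None = None
    n_features_: int = 0

    @property
    def classes_(self) -> np.ndarray:
        return self.estimator.classes_

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = _check_dim(self.n_features_, X, "SvmModel")
        return self.estimator.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """One-vs-one vote shares (rows sum to 1)."""
        X = _check_dim(self.n_features_, X, "SvmModel")
        df = self.estimator.decision_function(X)
        n_classes = self.estimator.classes_.size
        if n_classes == 2:
            votes = np.zeros((X.shape[0], 2))
            votes[:, 1] = df > 0
            votes[:, 0] = df <= 0
        else:
            votes = np.zeros((X.shape[0], n_classes))
            pair = 0
            for a in range(n_classes):
                for b in range(a + 1, n_classes):
                    win_a = df[:, pair] > 0
                    votes[win_a, a] += 1
                    votes[~win_a, b] += 1
                    pair += 1
        return votes / votes.sum(axis=1, keepdims=True)


def train_svm(X: np.ndarray, y: np.ndarray, kernel: str = "rbf",
              gamma: float | str = "auto-scale", C: float = 1.0) -> SvmModel:
    """Fit the SVM head.

    ``gamma='auto-scale'`` resolves to 1 / (d * Var(X)) over the training
    matrix; ``gamma='auto'`` to 1 / d; a float is used as-is.  Multiclass
    problems are decomposed one-vs-one with majority vote.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValidationError("SVM needs at least two classes")
    if kernel not in ("rbf", "linear"):
        raise ValidationError(f"kernel must be 'rbf' or 'linear', got {kernel!r}")
    d = X.shape[1]
    if gamma == "auto-scale" or gamma == "scale":
        var = X.var()
        resolved = 1.0 / (d * var) if var > 0 else 1.0 / d
    elif gamma == "auto":
        resolved = 1.0 / d
    else:
        resolved = float(gamma)
        if resolved <= 0:
            raise ValidationError(f"gamma must be positive, got {resolved}")
    est = SVC(kernel=kernel, gamma=resolved if kernel == "rbf" else "scale",
              C=C, decision_function_shape="ovo")
    est.fit(X, y)
    return SvmModel(estimator=est, kernel=kernel, gamma_resolved=resolved,
                    n_features_=d)


# ---------------------------------------------------------------------------
# generic predict


def predict(model, X: np.ndarray, return_scores: bool = False):
    """Uniform prediction across the three heads.

    Returns the label vector, or ``(labels, score_matrix)`` when
    ``return_scores`` is set; the score matrix rows are normalized class
    scores (softmax probabilities, Gaussian posteriors, or OvO vote shares).
    """
    labels = model.predict(X)
    if return_scores:
        return labels, model.predict_proba(X)
    return labels
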
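"""Scikit-learn style estimators.

`GroupGraphClassifier` is the subject-level classifier: it takes one
feature matrix (S_i x d, from a frozen image encoder) per subject,
builds the correlation graph per subject, runs the configured aggregate
encoder (GAT/GIN/MLP blocks or the MAX baseline) into global max
pooling and a multinomial-logit head, and is trained by mini-batch
Adam on the cross-entropy with a cosine-annealed learning rate.

`SplitConformalClassifier` wraps any (n, K) matrix of class
probabilities: `fit` calibrates the conformal threshold on held-out
scores and `predict_set` returns per-subject label sets with the
marginal coverage guarantee.

Both follow the sklearn estimator contract (get_params/set_params,
fitted attributes with trailing underscores) so they compose with
`sklearn.base.clone` and model-selection utilities; X is a list of
per-subject arrays rather than a rectangular matrix, as with other
estimators that consume variable-length inputs.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autodiff import Tensor
from .conformal import (
    CalibrationResult,
    ConformalConfig,
    calibrate_threshold,
    conformity_score,
    predict_set,
)
from .encoding import FeatureMatrix
from .graph import (
    DEFAULT_TAU,
    AggregateEncoderSpec,
    forward_subject,
    forward_tensor,
    init_params,
)

__all__ = ["GroupGraphClassifier", "SplitConformalClassifier"]


class _Adam:
    """Plain Adam over a dict of Tensors."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad[:] = 0.0


def _as_arrays(X) -> list[np.ndarray]:
    out = []
    for F in X:
        arr = F.features if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("each subject needs a 2-D (S, d) feature matrix with S >= 1")
        out.append(arr)
    return out


class GroupGraphClassifier(ClassifierMixin, BaseEstimator):
    """Correlation-graph aggregate classifier for grouped image features.

    Parameters
    ----------
    kind : {'gat', 'gin', 'mlp', 'max'}
        Aggregate encoder; 'mlp' and 'max' are the graph-free ablation
        baselines.
    n_blocks : {1, 2}
        Number of stacked encoder blocks (ignored for 'max').
    hidden_dim : int
        Inner dimension of the blocks (512 in production; tests use
        much smaller).
    heads : int
        Attention heads per GAT block (outputs concatenated).
    epsilon : float
        GIN self-weight term.
    tau : float
        Pearson-correlation threshold for linking two images.
    epochs, batch_size, base_lr : training schedule; Adam with cosine
        annealing of the learning rate from `base_lr` to ~0.
    standardize : bool
        Z-score each feature dimension on the training set before the
        graph (standard practice when training on frozen embeddings,
        whose scale is arbitrary). The correlation graph is built on the
        raw features either way, and standardization is a fixed
        per-dimension affine map, so permutation invariance is
        unaffected.
    seed : int
        Controls parameter init and batch shuffling.
    """

    def __init__(self, kind: str = "gat", n_blocks: int = 1, hidden_dim: int = 512,
                 heads: int = 1, epsilon: float = 0.0, tau: float = DEFAULT_TAU,
                 epochs: int = 100, batch_size: int = 32, base_lr: float = 1e-3,
                 standardize: bool = True, seed: int = 0):
        self.kind = kind
        self.n_blocks = n_blocks
        self.hidden_dim = hidden_dim
        self.heads = heads
        self.epsilon = epsilon
        self.tau = tau
        self.epochs = epochs
        self.batch_size = batch_size
        self.base_lr = base_lr
        self.standardize = standardize
        self.seed = seed

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y):
        """Train on a list of (S_i, d) arrays and subject labels."""
        feats = _as_arrays(X)
        y = np.asarray(y)
        if len(feats) != y.size or y.size == 0:
            raise ValueError("X and y must be equal-length and nonempty")
        self.classes_ = np.unique(y)
        K = self.classes_.size
        if K < 2:
            raise ValueError("need at least two classes")
        y_idx = np.searchsorted(self.classes_, y)
        counts = np.bincount(y_idx, minlength=K)
        if counts.max() != counts.min():
            import warnings

            warnings.warn("class counts are unbalanced; consider balanced_split",
                          UserWarning, stacklevel=2)
        d = feats[0].shape[1]
        if any(f.shape[1] != d for f in feats):
            raise ValueError("all subjects must share the feature dimension d")
        if self.standardize:
            stacked = np.vstack(feats)
            self.mean_ = stacked.mean(axis=0)
            self.scale_ = np.where(stacked.std(axis=0) > 0, stacked.std(axis=0), 1.0)
        else:
            self.mean_ = np.zeros(d)
            self.scale_ = np.ones(d)

        self.spec_ = AggregateEncoderSpec(kind=self.kind, n_blocks=self.n_blocks,
                                          hidden_dim=self.hidden_dim, heads=self.heads,
                                          epsilon=self.epsilon)
        self.params_ = init_params(self.spec_, d, K, seed=self.seed)
        rng = np.random.default_rng(self.seed + 1)
        opt = _Adam(self.params_, lr=self.base_lr)
        n = len(feats)
        self.loss_trace_ = []
        for epoch in range(self.epochs):
            # cosine annealing, per-epoch: base_lr -> ~0
            opt.lr = self.base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / self.epochs))
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                opt.zero_grad()
                loss = None
                for i in batch:
                    li = self._nll(feats[i], int(y_idx[i]))
                    loss = li if loss is None else loss + li
                loss = loss * (1.0 / len(batch))
                loss.backward()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "lower base_lr or inspect the features")
                opt.step()
                epoch_loss += float(loss.data) * len(batch)
            self.loss_trace_.append(epoch_loss / n)
        self.n_features_in_ = d
        return self

    def _nll(self, F: np.ndarray, k: int) -> Tensor:
        # node attributes standardized; graph built on the raw features
        logits = forward_tensor((F - self.mean_) / self.scale_, self.spec_,
                                self.params_, self.tau, F_graph=F)  # (1, K)
        shift = Tensor(logits.data.max())  # constant: stabilises logsumexp
        z = logits - shift
        lse = z.exp().sum().log()
        pick = np.zeros((logits.shape[1], 1))
        pick[k, 0] = 1.0
        return lse - (z @ Tensor(pick)).sum()

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        feats = _as_arrays(X)
        return np.stack([
            forward_subject((F - self.mean_) / self.scale_, self.spec_, self.params_,
                            self.tau, F_graph=F).sigma
            for F in feats
        ])

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("classifier is not fitted")


class SplitConformalClassifier(BaseEstimator):
    """Split-conformal prediction sets over class-probability rows.

    `fit(P_cal, y_cal)` computes conformity scores on the calibration
    probabilities and stores the threshold q̂; `predict_set(P)` returns
    one sorted array of 1-based class indices per row. With
    method='nps' no calibration is used (fit still validates input).
    """

    def __init__(self, method: str = "aps", alpha: float = 0.1, lam: float = 0.01,
                 k_reg: int = 1, randomized: bool = True, allow_empty: bool = False,
                 seed: int = 0):
        self.method = method
        self.alpha = alpha
        self.lam = lam
        self.k_reg = k_reg
        self.randomized = randomized
        self.allow_empty = allow_empty
        self.seed = seed

    def _cfg(self) -> ConformalConfig:
        return ConformalConfig(method=self.method, alpha=self.alpha, lam=self.lam,
                               k_reg=self.k_reg, randomized=self.randomized,
                               allow_empty=self.allow_empty, seed=self.seed)

    def fit(self, P, y):
        P = np.asarray(P, dtype=float)
        y = np.asarray(y)
        if P.ndim != 2 or P.shape[0] != y.size:
            raise ValueError("P must be (n, K) with one label per row")
        cfg = self._cfg()
        if cfg.method == "nps":
            self.result_ = None
        else:
            rng = np.random.default_rng(self.seed)
            scores = [
                conformity_score(P[i], int(y[i]), cfg, u=float(rng.random()))
                for i in range(P.shape[0])
            ]
            self.result_ = calibrate_threshold(np.asarray(scores), cfg.alpha)
        self.n_features_in_ = P.shape[1]
        return self

    def predict_set(self, P) -> list[np.ndarray]:
        if not hasattr(self, "result_"):
            raise RuntimeError("conformal classifier is not fitted")
        P = np.asarray(P, dtype=float)
        cfg = self._cfg()
        rng = np.random.default_rng(self.seed + 1)
        return [predict_set(P[i], self.result_, cfg, u=float(rng.random()))
                for i in range(P.shape[0])]

    @property
    def q_hat_(self) -> float:
        res: CalibrationResult | None = getattr(self, "result_", None)
        if res is None:
            raise AttributeError("no threshold: unfitted or method='nps'")
        return res.q_hat
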
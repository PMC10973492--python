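"""Split-conformal prediction sets for the classifier (NPS/APS/RAPS).

Given class scores σ from any probabilistic classifier and an
exchangeable calibration set, split conformal prediction returns, for
each test subject, a *set* of labels guaranteed to contain the true one
with probability at least 1 − α. The conformity score of a sample is
the cumulative softmax mass needed to reach its true label when labels
are ranked by descending score:

* APS  — cum(r−1) + u·σ_label with u ~ U(0,1) (u = 1 when the
  randomised mechanism is off); r is the rank of the true label.
* RAPS — the APS score plus a rank penalty λ·max(0, r − k_reg) that
  discourages large sets.
* NPS  — the naive baseline: the smallest prefix of descending scores
  whose mass reaches 1 − α; no calibration, no finite-sample guarantee.

Calibration uses the conservative order statistic: q̂ is the
⌈(n+1)(1−α)⌉-th smallest calibration score (+∞ if the index overflows,
which forces full sets). Test-time sets include labels in descending
score order while their own cumulative (penalised) score stays ≤ q̂;
the top-ranked label is always kept unless empty sets are explicitly
allowed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthetic import gen_calibrated_scores

__all__ = [
    "ConformalConfig",
    "CalibrationResult",
    "CoverageReport",
    "conformity_score",
    "calibrate_threshold",
    "predict_set",
    "coverage_report",
    "coverage_simulation",
]


@dataclass
class ConformalConfig:
    method: str = "aps"  # nps | aps | raps
    alpha: float = 0.1
    lam: float = 0.01  # RAPS penalty λ
    k_reg: int = 1  # RAPS rank offset
    randomized: bool = True
    allow_empty: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.method not in {"nps", "aps", "raps"}:
            raise ValueError(f"unknown method {self.method!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class CalibrationResult:
    q_hat: float  # may be +inf
    n_cal: int
    method: str


@dataclass
class CoverageReport:
    mean_set_size: float
    coverage_all: float
    coverage_unambiguous: float  # singleton sets; nan when the group is empty
    coverage_ambiguous: float  # multi-label sets; nan when the group is empty
    n_unambiguous: int
    n_ambiguous: int


def _rank_of(sigma: np.ndarray, label: int) -> tuple[np.ndarray, int]:
    """Descending-score order (stable; ties broken by ascending label
    index) and the 1-based rank of `label` in it."""
    order = np.argsort(-sigma, kind="stable")
    rank = int(np.nonzero(order == label - 1)[0][0]) + 1
    return order, rank


def conformity_score(sigma: np.ndarray, label: int,
                     cfg: ConformalConfig, u: float = 1.0) -> float:
    """APS/RAPS conformity score for one (scores, true label) pair."""
    sigma = np.asarray(sigma, dtype=np.float64)
    K = sigma.size
    if not 1 <= label <= K:
        raise ValueError(f"label {label} out of range 1..{K}")
    order, rank = _rank_of(sigma, label)
    cum_above = float(sigma[order[: rank - 1]].sum())
    uu = u if cfg.randomized else 1.0
    score = cum_above + uu * float(sigma[label - 1])
    if cfg.method == "raps":
        score += cfg.lam * max(0, rank - cfg.k_reg)
    return score


def calibrate_threshold(cal_scores: np.ndarray, alpha: float) -> CalibrationResult:
    """q̂ = the ⌈(n+1)(1−α)⌉-th smallest calibration score, or +∞."""
    cal_scores = np.asarray(cal_scores, dtype=np.float64)
    n = cal_scores.size
    if n < 1:
        raise ValueError("empty calibration set")
    idx = math.ceil((n + 1) * (1.0 - alpha))
    if idx > n:
        q = math.inf
    else:
        q = float(np.sort(cal_scores)[idx - 1])
    return CalibrationResult(q_hat=q, n_cal=n, method="")


def predict_set(sigma: np.ndarray, result: CalibrationResult | None,
                cfg: ConformalConfig, u: float = 1.0) -> np.ndarray:
    """Labels (1-based, ascending) in the conformal prediction set."""
    sigma = np.asarray(sigma, dtype=np.float64)
    K = sigma.size
    order = np.argsort(-sigma, kind="stable")
    uu = u if cfg.randomized else 1.0

    if cfg.method == "nps":
        # smallest prefix of descending scores with mass >= 1 - alpha
        cum = np.cumsum(sigma[order])
        k = int(np.searchsorted(cum, 1.0 - cfg.alpha - 1e-12) + 1)
        members = order[: min(k, K)] + 1
        return np.sort(members)

    if result is None:
        raise ValueError(f"{cfg.method} requires a calibrated threshold")
    q = result.q_hat
    cum_above = 0.0
    members = []
    for r, j in enumerate(order, start=1):
        s = cum_above + uu * float(sigma[j])
        if cfg.method == "raps":
            s += cfg.lam * max(0, r - cfg.k_reg)
        if s <= q:
            members.append(j + 1)
        else:
            break  # scores along ranks are nondecreasing: stop at first failure
        cum_above += float(sigma[j])
    if not members and not cfg.allow_empty:
        members = [int(order[0]) + 1]
    return np.sort(np.asarray(members, dtype=int))


def coverage_report(sets: list[np.ndarray], labels: np.ndarray) -> CoverageReport:
    """Mean set size and coverage overall / within the singleton
    (unambiguous) and multi-label (ambiguous) groups."""
    labels = np.asarray(labels)
    if len(sets) != labels.size or labels.size == 0:
        raise ValueError("sets and labels must be equal-length and nonempty")
    sizes = np.array([len(s) for s in sets])
    covered = np.array([lab in s for s, lab in zip(sets, labels)])
    single = sizes == 1
    multi = sizes > 1

    def _rate(mask):
        return float(covered[mask].mean()) if mask.any() else float("nan")

    return CoverageReport(
        mean_set_size=float(sizes.mean()),
        coverage_all=float(covered.mean()),
        coverage_unambiguous=_rate(single),
        coverage_ambiguous=_rate(multi),
        n_unambiguous=int(single.sum()),
        n_ambiguous=int(multi.sum()),
    )


def coverage_simulation(
    cfg: ConformalConfig,
    K: int = 4,
    concentration: float | np.ndarray = 1.0,
    n_cal: int = 500,
    n_test: int = 5000,
    n_reps: int = 100,
    seed: int = 0,
) -> dict:
    """Monte-Carlo check of the marginal coverage guarantee.

    Each replicate draws fresh oracle-calibrated (score, label) pairs,
    calibrates q̂ on `n_cal` of them and evaluates prediction sets on
    `n_test` more; returns mean coverage and set size with the
    Monte-Carlo standard error across replicates.
    """
    if min(n_cal, n_test, n_reps) < 1:
        raise ValueError("sizes must be >= 1")
    root = np.random.default_rng(seed)
    coverages, sizes = [], []
    for _ in range(n_reps):
        rep_seed = int(root.integers(2**31))
        samples = gen_calibrated_scores(n_cal + n_test, K=K,
                                        concentration=concentration, seed=rep_seed)
        urng = np.random.default_rng(rep_seed + 1)
        cal, test = samples[:n_cal], samples[n_cal:]
        if cfg.method == "nps":
            result = None
        else:
            cal_scores = [
                conformity_score(s.scores, s.label, cfg, u=float(urng.random()))
                for s in cal
            ]
            result = calibrate_threshold(np.asarray(cal_scores), cfg.alpha)
        sets = [
            predict_set(s.scores, result, cfg, u=float(urng.random())) for s in test
        ]
        rep = coverage_report(sets, np.array([s.label for s in test]))
        coverages.append(rep.coverage_all)
        sizes.append(rep.mean_set_size)
    coverages = np.asarray(coverages)
    sizes = np.asarray(sizes)

    def _se(x):
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    return {
        "mean_coverage": float(coverages.mean()),
        "se_coverage": _se(coverages),
        "mean_set_size": float(sizes.mean()),
        "se_set_size": _se(sizes),
        "n_reps": n_reps,
    }
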
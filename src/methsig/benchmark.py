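"""Ground-truth benchmark metrics, label-permutation false-positive
rates, the precision/H-score relation, and the cross-method rank test.

Metrics are computed against the spike-in simulator's truth over the
universe of covered, filter-surviving sites: tp = |sig ∩ truth|,
fp = |sig \\ truth|, fn = |truth \\ sig|, tn = the rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GroupAssignment, MethylMatrix, Signature
from .hobotnica import STATUS_OK, h_score, signature_distance_matrix
from .simulate import SimulationTruth, make_mixed_signature

__all__ = [
    "BenchmarkMetrics",
    "confusion_metrics",
    "label_permutation_fpr",
    "precision_hscore_curve",
    "compare_methods",
]


@dataclass(frozen=True)
class BenchmarkMetrics:
    """Confusion counts and the derived rates.

    ``precision`` is None when the signature is empty (tp + fp = 0);
    ``fpr`` is None when fp + tn = 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def fpr(self) -> float | None:
        d = self.fp + self.tn
        return self.fp / d if d else None


def confusion_metrics(
    signature: Signature | Iterable[str],
    truth: SimulationTruth,
    universe: Iterable[str] | None = None,
) -> BenchmarkMetrics:
    """Confusion counts of a signature against simulation truth.

    ``universe`` defaults to the truth's recorded site universe; pass
    the post-filter site set when filters shrank it. Signature sites
    outside the universe raise.
    """
    sig = pd.Index(signature.sites if isinstance(signature, Signature) else list(signature))
    uni = pd.Index(universe) if universe is not None else truth.universe
    stray = sig.difference(uni)
    if len(stray):
        raise ValueError(f"signature sites outside the universe: {list(stray[:5])}")
    true = pd.Index(truth.true_sites).intersection(uni)
    tp = len(sig.intersection(true))
    fp = len(sig) - tp
    fn = len(true) - tp
    tn = len(uni) - tp - fp - fn
    return BenchmarkMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def label_permutation_fpr(
    data,
    groups: GroupAssignment,
    pipeline: Callable[[object, GroupAssignment], Signature],
    n_perm: int = 1,
    seed: int | np.random.Generator | None = None,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """False-positive rate after randomly permuting the group labels.

    ``pipeline`` maps (data, permuted groups) to a Signature (typically
    filter -> test -> build_signature). Every site the permuted analysis
    calls is a false positive; the remaining covered sites are true
    negatives, so fpr = |sig| / |universe|. Returns one row per
    permutation (the benchmark default is a single permutation;
    aggregate over more for a stabler estimate).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for k in range(n_perm):
        perm = groups.permuted(rng)
        sig = pipeline(data, perm)
        uni = pd.Index(universe) if universe is not None else _universe_of(data)
        n_called = len(sig)
        rows.append(
            {
                "perm": k,
                "n_called": n_called,
                "universe": len(uni),
                "fpr": n_called / len(uni) if len(uni) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _universe_of(data) -> pd.Index:
    if isinstance(data, MethylMatrix):
        return data.sites
    return data.site_keys  # CountTable


def precision_hscore_curve(
    matrix: MethylMatrix,
    groups: GroupAssignment,
    truth: SimulationTruth,
    length: int,
    fractions: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    reps: int = 10,
    seed: int | np.random.Generator | None = None,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Mean H-score of mixed true/false-positive signatures by
    true-positive fraction.

    For each fraction, ``reps`` random signatures of the given length
    are assembled from truth and non-truth sites, scored, and
    aggregated. Returns columns: fraction, precision (mean over reps),
    h_mean, h_sd, and the per-rep H values (as a list column ``h``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uni = pd.Index(universe) if universe is not None else truth.universe
    uni = uni.intersection(matrix.sites)
    rows = []
    for frac in fractions:
        hs = []
        precs = []
        for _ in range(reps):
            sig = make_mixed_signature(truth, uni, length, frac, seed=rng)
            res = h_score(signature_distance_matrix(matrix, sig), groups)
            hs.append(res.h if res.status == STATUS_OK else 0.0)
            precs.append(confusion_metrics(sig, truth, uni).precision)
        rows.append(
            {
                "fraction": frac,
                "precision": float(np.mean(precs)),
                "h_mean": float(np.mean(hs)),
                "h_sd": float(np.std(hs, ddof=1)) if len(hs) > 1 else 0.0,
                "h": hs,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MethodComparison:
    """Shapiro-Wilk normality per method plus the Friedman rank test
    across the methods x datasets block."""

    shapiro: pd.DataFrame
    friedman_statistic: float
    friedman_p: float


def compare_methods(h_table: pd.DataFrame) -> MethodComparison:
    """Compare methods by their H-scores across datasets.

    ``h_table`` is a complete methods (rows) x datasets (columns) block
    of H-scores; zeros are legitimate values and stay in. Normality of
    each method's H-score distribution is screened with Shapiro-Wilk;
    the methods are then compared with the Friedman rank test
    (asymptotic chi-square reference, average ranks for ties).
    """
    if h_table.shape[0] < 2:
        raise ValueError("need at least two methods")
    if h_table.shape[1] < 2:
        raise ValueError("need at least two datasets")
    if h_table.isna().any().any():
        raise ValueError("H-score block must be complete (no missing entries)")
    sh_rows = []
    for method, vals in h_table.iterrows():
        v = vals.to_numpy(float)
        if len(np.unique(v)) < 2 or len(v) < 3:
            w, p = np.nan, np.nan
        else:
            w, p = stats.shapiro(v)
        sh_rows.append({"method": method, "W": w, "p": p})
    stat, p = _friedman(h_table.to_numpy(float))
    return MethodComparison(
        shapiro=pd.DataFrame(sh_rows).set_index("method"),
        friedman_statistic=stat,
        friedman_p=p,
    )


def _friedman(block: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square over a k methods x n datasets
    block, with the asymptotic chi-square(k-1) p-value. A block whose
    columns are all fully tied (no discrimination at all) is reported as
    statistic 0, p 1 rather than the 0/0 of the textbook formula."""
    k, n = block.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, block)  # rank methods per dataset
    R = ranks.sum(axis=1)
    s = 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for j in range(n):
        _, counts = np.unique(block[:, j], return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:
        return 0.0, 1.0
    statistic = s / c
    return float(statistic), float(stats.chi2.sf(statistic, df=k - 1))
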
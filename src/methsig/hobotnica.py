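"""Rank-based signature separation score (H-score) with an empirical
permutation null.

The H-score of a signature on a dataset measures how completely
between-group sample distances exceed within-group distances when
samples are represented by their methylation levels at the signature's
sites. All n(n-1)/2 pairwise distances are ranked ascending (average
ranks for ties); with R the rank sum over the b between-group pairs and
w the number of within-group pairs,

    H = (R - b(b+1)/2) / (b * w)

which lies in [0, 1]: 1 means every between-group distance exceeds
every within-group distance (perfect separation), 0 the reverse, and
0.5 the exchangeable-null level. H equals the Mann-Whitney U statistic
of between- versus within-group distances scaled to [0, 1], and is
invariant under any strictly increasing transform of the distances.

Scoring conventions for degenerate inputs: a distance matrix with a
missing entry (two samples sharing no jointly covered signature site)
scores 0 with status ``zero_na_rule``; signatures shorter than two
sites score 0 with status ``zero_short_signature``.

Statistical significance is an empirical p-value against H-scores of
random same-length signatures drawn from the dataset's site universe,
with a pseudo-count: p = (#{H_null >= H_obs} + 1) / (n_used + 1).
Zero-status null draws are discarded; by default sampling continues (to
a cap) until the requested null count is reached, and the p-value is
reported undefined if it cannot be.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .containers import GroupAssignment, MethylMatrix, Signature

__all__ = [
    "DistanceMatrix",
    "HScoreResult",
    "signature_distance_matrix",
    "h_score",
    "h_score_pvalue",
    "evaluate_signature",
]

STATUS_OK = "ok"
STATUS_ZERO_NA = "zero_na_rule"
STATUS_ZERO_SHORT = "zero_short_signature"


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix; NaN marks pairs whose
    distance is undefined (no shared covered site)."""

    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.samples):
            raise ValueError("distance matrix shape does not match samples")
        if not np.allclose(np.diag(v), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.any(v[~np.isnan(v)] < 0):
                raise ValueError("distances must be non-negative")
        vt = v.T
        both = ~(np.isnan(v) | np.isnan(vt))
        if not np.allclose(v[both], vt[both]):
            raise ValueError("matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.samples)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def _sites_of(signature) -> list[str]:
    if isinstance(signature, Signature):
        return signature.sites
    return list(signature)


def signature_distance_matrix(
    matrix: MethylMatrix,
    signature,
    metric: str = "euclidean",
) -> DistanceMatrix:
    """Pairwise sample distances over the signature's sites.

    Each pair of samples is compared over the sites where both are
    non-missing (pairwise-complete Euclidean distance); a pair with no
    shared site gets a NaN entry, which forces H = 0 downstream.
    """
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    sites = _sites_of(signature)
    missing = pd.Index(sites).difference(matrix.sites)
    if len(missing):
        raise KeyError(f"signature sites absent from matrix: {list(missing[:10])}")
    sub = matrix.values.loc[sites].to_numpy(float)
    n = sub.shape[1]
    if not np.isnan(sub).any():
        d = squareform(pdist(sub.T, metric="euclidean"))
        return DistanceMatrix(d, matrix.samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(np.isnan(sub[:, i]) | np.isnan(sub[:, j]))
            if not both.any():
                d[i, j] = d[j, i] = np.nan
            else:
                diff = sub[both, i] - sub[both, j]
                d[i, j] = d[j, i] = float(np.sqrt(np.sum(diff * diff)))
    return DistanceMatrix(d, matrix.samples)


@dataclass
class HScoreResult:
    """H-score with its status and (optional) empirical p-value."""

    h: float
    status: str = STATUS_OK
    p_value: float | None = None
    n_null: int = 0
    null_h: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.status == STATUS_OK:
            if not (-1e-9 <= self.h <= 1 + 1e-9):
                raise ValueError(f"H outside [0,1]: {self.h}")
            self.h = float(min(max(self.h, 0.0), 1.0))
        elif self.h != 0.0:
            raise ValueError("non-ok status requires h = 0")


def _between_mask(labels: np.ndarray) -> np.ndarray:
    """Condensed-order boolean mask of between-group sample pairs."""
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    return labels[iu] != labels[ju]


def _h_from_condensed(d: np.ndarray, between: np.ndarray) -> float:
    ranks = rankdata(d, method="average")
    b = int(between.sum())
    w = len(d) - b
    r = float(ranks[between].sum())
    h = (r - b * (b + 1) / 2.0) / (b * w)
    return float(min(max(h, 0.0), 1.0))


def h_score(D: DistanceMatrix, groups: GroupAssignment) -> HScoreResult:
    """H-score of a distance matrix under a group assignment.

    Requires two or more groups with at least two samples each (so both
    between- and within-group pairs exist). Any missing distance entry
    triggers the zero rule (status ``zero_na_rule``).
    """
    labels = groups.labels_for(D.samples)
    for lab in np.unique(labels):
        if (labels == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than two samples")
    d = D.condensed()
    if np.isnan(d).any():
        return HScoreResult(0.0, status=STATUS_ZERO_NA)
    between = _between_mask(labels)
    return HScoreResult(_h_from_condensed(d, between))


def h_score_pvalue(
    matrix: MethylMatrix,
    groups: GroupAssignment,
    length: int,
    observed_h: float | HScoreResult,
    n_null: int = 5000,
    max_attempts: int = 50_000,
    seed: int | np.random.Generator | None = None,
    sites_with_replacement: bool = False,
    strict_attempts: bool = False,
    return_null: bool = False,
):
    """Empirical p-value of an observed H against random signatures.

    Random signatures of the given length are drawn from the matrix's
    site universe (without replacement within one signature by default;
    ``sites_with_replacement=True`` selects the literal
    with-replacement reading, in which case repeated sites collapse).
    Null draws whose H is zero by rule are discarded. Sampling runs
    until ``n_null`` retained values or ``max_attempts`` draws
    (``strict_attempts=True`` stops at exactly ``n_null`` draws and
    voids the p-value if any were discarded). The p-value uses a
    pseudo-count: p = (#{H_null >= H_obs} + 1) / (n_used + 1); if fewer
    than ``n_null`` null values were retained the p-value is undefined
    (None).

    Returns ``(p, n_used)``, or ``(p, n_used, null_h)`` with
    ``return_null=True``.
    """
    if length < 2:
        raise ValueError("signature length must be >= 2 (zero rule applies to shorter)")
    if isinstance(observed_h, HScoreResult):
        if observed_h.status != STATUS_OK:
            raise ValueError("observed H-score must have status ok")
        obs = observed_h.h
    else:
        obs = float(observed_h)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = groups.labels_for(matrix.samples)
    between = _between_mask(labels)
    values = matrix.values.to_numpy(float)
    n_sites = values.shape[0]
    if n_sites < 2:
        raise ValueError("site universe too small")
    has_nan = np.isnan(values).any()

    null_h: list[float] = []
    attempts = 0
    budget = n_null if strict_attempts else max_attempts
    while len(null_h) < n_null and attempts < budget:
        attempts += 1
        if sites_with_replacement:
            rows = np.unique(rng.integers(0, n_sites, size=length))
            if len(rows) < 2:
                continue
        else:
            rows = rng.choice(n_sites, size=length, replace=False)
        sub = values[rows]
        if has_nan and np.isnan(sub).any():
            dm = signature_distance_matrix(
                MethylMatrix(matrix.values.iloc[rows]), matrix.values.index[rows]
            )
            d = dm.condensed()
            if np.isnan(d).any():
                continue
        else:
            d = pdist(sub.T, metric="euclidean")
        null_h.append(_h_from_condensed(d, between))
    n_used = len(null_h)
    arr = np.asarray(null_h)
    if n_used < n_null:
        p = None
    else:
        p = (int(np.sum(arr >= obs)) + 1) / (n_used + 1)
    if return_null:
        return p, n_used, arr
    return p, n_used


def evaluate_signature(
    matrix: MethylMatrix,
    groups: GroupAssignment,
    signature: Signature,
    subsets: Sequence = ("full", 100, 10),
    n_null: int = 0,
    max_attempts: int = 50_000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Score a signature and its top-N subsets.

    Returns one row per subset: subset label, length, H, status, p-value
    (NaN unless ``n_null`` > 0 and defined) and the null-sample count.
    Empty and single-site (sub)signatures score 0 with status
    ``zero_short_signature``; the p-value machinery only runs for
    status-ok scores.
    """
    from .signatures import top_n

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for subset in subsets:
        sub_sig = signature if subset == "full" else top_n(signature, int(subset))
        length = len(sub_sig)
        if length < 2:
            res = HScoreResult(0.0, status=STATUS_ZERO_SHORT)
        else:
            D = signature_distance_matrix(matrix, sub_sig)
            res = h_score(D, groups)
        p: float | None = None
        n_used = 0
        if n_null > 0 and res.status == STATUS_OK:
            p, n_used = h_score_pvalue(
                matrix, groups, length, res, n_null=n_null, max_attempts=max_attempts, seed=rng
            )
        rows.append(
            {
                "subset": str(subset),
                "length": length,
                "h": res.h,
                "status": res.status,
                "p_value": np.nan if p is None else p,
                "n_null": n_used,
            }
        )
    return pd.DataFrame(rows)
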
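"""Site-level coverage and group-presence filters for bisulfite counts,
and conversion of counts to methylation ratios."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountTable, GroupAssignment, MethylMatrix

__all__ = [
    "filter_by_coverage",
    "filter_by_group_presence",
    "methylation_ratios",
]


def filter_by_coverage(counts: CountTable, min_reads: int = 5, strict: bool = True) -> CountTable:
    """Mask low-coverage cells and drop sites with no covered sample left.

    With ``strict=True`` (default) a cell is kept only when its coverage
    is strictly greater than ``min_reads``; with ``strict=False`` the
    threshold is inclusive (coverage >= min_reads). Masked cells are set
    to meth=0, cov=0 (the missing sentinel).
    """
    keep = counts.cov > min_reads if strict else counts.cov >= min_reads
    meth = np.where(keep, counts.meth, 0)
    cov = np.where(keep, counts.cov, 0)
    any_covered = cov.sum(axis=1) > 0
    return CountTable(counts.sites.loc[any_covered], counts.samples, meth[any_covered], cov[any_covered])


def filter_by_group_presence(
    counts: CountTable,
    groups: GroupAssignment,
    max_uncovered_per_group: int = 1,
    rule: str = "uncovered_in_every_group",
) -> CountTable:
    """Drop sites with too many uncovered samples.

    Two readings of the presence rule are offered:

    - ``"uncovered_in_every_group"`` (default): a site is discarded when
      the number of uncovered samples exceeds ``max_uncovered_per_group``
      in *every* group — i.e. with the default of 1, discarded iff at
      least two samples are uncovered in each group.
    - ``"min_covered_per_group"``: a site is kept only when every group
      has at least ``max_uncovered_per_group + 1`` covered samples (the
      stricter, commonly used alternative).

    A cell is uncovered when cov == 0 (apply ``filter_by_coverage``
    first so low-coverage cells count as uncovered).
    """
    if rule not in ("uncovered_in_every_group", "min_covered_per_group"):
        raise ValueError(f"unknown rule {rule!r}")
    labels = groups.labels_for(counts.samples)
    uncovered = counts.cov == 0
    n_groups = len(groups.labels)
    uncov_per_group = np.empty((counts.n_sites, n_groups), dtype=np.int64)
    size_per_group = np.empty(n_groups, dtype=np.int64)
    for gi, lab in enumerate(groups.labels):
        cols = labels == lab
        size_per_group[gi] = cols.sum()
        uncov_per_group[:, gi] = uncovered[:, cols].sum(axis=1)
    if np.any(size_per_group < max_uncovered_per_group + 1):
        small = [g for g, n in zip(groups.labels, size_per_group) if n < max_uncovered_per_group + 1]
        raise ValueError(
            f"groups {small} have fewer than {max_uncovered_per_group + 1} samples; presence rule undecidable"
        )
    if rule == "uncovered_in_every_group":
        discard = np.all(uncov_per_group > max_uncovered_per_group, axis=1)
        keep = ~discard
    else:
        covered = size_per_group[None, :] - uncov_per_group
        keep = np.all(covered >= max_uncovered_per_group + 1, axis=1)
    return CountTable(counts.sites.loc[keep], counts.samples, counts.meth[keep], counts.cov[keep])


def methylation_ratios(counts: CountTable) -> MethylMatrix:
    """Per-cell methylation ratio meth/cov; cells with cov == 0 are missing."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(counts.cov > 0, counts.meth / np.maximum(counts.cov, 1), np.nan)
    return MethylMatrix(pd.DataFrame(ratio, index=counts.site_keys, columns=counts.samples))
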
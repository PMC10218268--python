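"""Core in-memory containers shared across the pipeline.

Positions are 1-based internally; BED export converts to 0-based
half-open. A site is identified by its ``chrom:pos`` key (strand is
carried but not part of the key unless strand-collapsing is disabled at
read time, in which case reverse-strand sites keep a ``:-`` suffix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "site_key",
    "CountTable",
    "MethylMatrix",
    "GroupAssignment",
    "DMResult",
    "Signature",
]


def site_key(chrom: str, pos: int, strand: str = ".", collapse_strand: bool = True) -> str:
    """Canonical site identifier. With strand collapsing (default) the key
    is ``chrom:pos``; otherwise reverse-strand sites get ``chrom:pos:-``."""
    if collapse_strand or strand in (".", "+", "", None):
        return f"{chrom}:{pos}"
    return f"{chrom}:{pos}:{strand}"


class CountTable:
    """Per-site, per-sample methylated/total read counts.

    Parameters
    ----------
    sites : DataFrame with columns ``chrom``, ``pos`` (1-based), ``strand``,
        indexed by the canonical site key.
    samples : ordered, unique sample names.
    meth, cov : ``(n_sites, n_samples)`` non-negative integer arrays with
        ``meth <= cov`` elementwise. ``cov == 0`` marks a missing cell.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        samples: Sequence[str],
        meth: np.ndarray,
        cov: np.ndarray,
    ) -> None:
        samples = list(samples)
        meth = np.asarray(meth, dtype=np.int64)
        cov = np.asarray(cov, dtype=np.int64)
        if len(samples) != len(set(samples)):
            raise ValueError("duplicate sample names")
        if sites.index.has_duplicates:
            dups = sites.index[sites.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sites: {dups[:5]}")
        if meth.shape != (len(sites), len(samples)) or cov.shape != meth.shape:
            raise ValueError(
                f"shape mismatch: {len(sites)} sites x {len(samples)} samples "
                f"vs meth {meth.shape}, cov {cov.shape}"
            )
        if (meth < 0).any() or (cov < 0).any():
            raise ValueError("counts must be non-negative")
        if (meth > cov).any():
            raise ValueError("meth > cov at some cells")
        self.sites = sites
        self.samples = samples
        self.meth = meth
        self.cov = cov

    # -- basic introspection -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def site_keys(self) -> pd.Index:
        return self.sites.index

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountTable({self.n_sites} sites, {self.n_samples} samples)"

    # -- manipulation --------------------------------------------------------
    def subset_sites(self, selector) -> "CountTable":
        """Row subset by boolean mask or list of site keys (order preserved)."""
        if isinstance(selector, (pd.Series, np.ndarray, list)) and len(selector) == self.n_sites and (
            np.asarray(selector).dtype == bool
        ):
            mask = np.asarray(selector, dtype=bool)
            return CountTable(self.sites.loc[mask], self.samples, self.meth[mask], self.cov[mask])
        keys = pd.Index(selector)
        missing = keys.difference(self.site_keys)
        if len(missing):
            raise KeyError(f"sites not in table: {list(missing[:5])}")
        idx = self.site_keys.get_indexer(keys)
        return CountTable(self.sites.iloc[idx], self.samples, self.meth[idx], self.cov[idx])

    def sorted_by_position(self) -> "CountTable":
        order = np.lexsort((self.sites["pos"].to_numpy(), self.sites["chrom"].to_numpy()))
        return CountTable(self.sites.iloc[order], self.samples, self.meth[order], self.cov[order])

    @staticmethod
    def from_frames(meth: pd.DataFrame, cov: pd.DataFrame, sites: pd.DataFrame | None = None) -> "CountTable":
        """Build from aligned meth/cov DataFrames (index = site keys)."""
        if not meth.index.equals(cov.index) or list(meth.columns) != list(cov.columns):
            raise ValueError("meth and cov frames must be aligned")
        if sites is None:
            parts = meth.index.str.split(":")
            sites = pd.DataFrame(
                {
                    "chrom": [p[0] for p in parts],
                    "pos": [int(p[1]) for p in parts],
                    "strand": ".",
                },
                index=meth.index,
            )
        return CountTable(sites, list(meth.columns), meth.to_numpy(), cov.to_numpy())


class MethylMatrix:
    """Site x sample methylation levels in [0, 1].

    Backed by a float DataFrame; ``NaN`` is the missing-value sentinel
    (0.0 is a legitimate methylation level and never means missing).
    """

    def __init__(self, values: pd.DataFrame) -> None:
        vals = values.astype(float)
        arr = vals.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if np.nansum(bad) > 0:
            r, c = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"methylation level out of [0,1] at site {vals.index[r]!r}, sample {vals.columns[c]!r}: {arr[r, c]}"
            )
        if vals.index.has_duplicates:
            raise ValueError("duplicate site identifiers")
        if vals.columns.has_duplicates:
            raise ValueError("duplicate sample names")
        self.values = vals

    @property
    def sites(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_sites(self) -> int:
        return len(self.values)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MethylMatrix({self.n_sites} sites, {len(self.samples)} samples)"

    def subset(self, keys: Iterable[str]) -> "MethylMatrix":
        keys = pd.Index(keys)
        missing = keys.difference(self.sites)
        if len(missing):
            raise KeyError(f"sites not in matrix: {list(missing[:5])}")
        return MethylMatrix(self.values.loc[keys])


@dataclass(frozen=True)
class GroupAssignment:
    """Mapping sample name -> group label (two or more groups)."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("need at least two groups")

    @property
    def labels(self) -> list[str]:
        # deterministic order: sorted unique labels
        return sorted(set(self.mapping.values()))

    @property
    def samples(self) -> list[str]:
        return list(self.mapping)

    def group_of(self, sample: str) -> str:
        return self.mapping[sample]

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == label]

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        missing = [s for s in samples if s not in self.mapping]
        if missing:
            raise KeyError(f"samples without group label: {missing[:5]}")
        return np.array([self.mapping[s] for s in samples])

    def require_min_group_size(self, k: int) -> None:
        for lab in self.labels:
            n = len(self.members(lab))
            if n < k:
                raise ValueError(f"group {lab!r} has {n} samples; at least {k} required")

    def permuted(self, rng: np.random.Generator) -> "GroupAssignment":
        """Randomly reassign the existing labels across the same samples
        (label multiset preserved)."""
        samples = self.samples
        labs = [self.mapping[s] for s in samples]
        perm = rng.permutation(len(samples))
        return GroupAssignment({s: labs[i] for s, i in zip(samples, perm)})


@dataclass
class DMResult:
    """Per-site differential methylation test output.

    ``table`` is indexed by site key with columns ``statistic``, ``p``,
    ``p_adj`` (and/or ``posterior``), ``mean_g1``, ``mean_g2``, ``diff``
    where ``diff = mean_g2 - mean_g1``. Undefined p-values are ``NaN``.
    """

    table: pd.DataFrame
    group1: str
    group2: str
    method: str

    def __post_init__(self) -> None:
        for col in ("p", "p_adj"):
            if col in self.table.columns:
                v = self.table[col].to_numpy(float)
                with np.errstate(invalid="ignore"):
                    if np.any((v < 0) | (v > 1)):
                        raise ValueError(f"{col} outside [0,1]")
        if "diff" in self.table.columns:
            d = self.table["diff"].to_numpy(float)
            with np.errstate(invalid="ignore"):
                if np.any(np.abs(d) > 1 + 1e-12):
                    raise ValueError("difference outside [-1,1]")

    @property
    def sites(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Signature:
    """Ordered list of DM sites with their scores and effect directions.

    ``table`` is indexed by site key in signature (sort) order, with
    columns ``score`` (adjusted p or posterior), ``diff`` and
    ``direction`` (hyper/hypo/na). ``provenance`` records the method tag
    and thresholds used to build the signature.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sites in signature")

    @property
    def sites(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:  # pragma: no cover
        tag = self.provenance.get("method", "?")
        return f"Signature({len(self)} sites, method={tag})"
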
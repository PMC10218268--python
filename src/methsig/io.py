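"""Readers and writers for the methylation formats the pipeline touches.

Supported formats: Bismark coverage files (``.cov`` / ``.cov.gz``),
bedGraph-style count files, TSV beta-value matrices, TSV sample sheets,
TSV/BED signature exports, wide-format count tables, and delimited
tables of external differential-methylation results (methylKit, DSS,
limma, HMM-DM style output imported through a column map).

Coordinate conventions: Bismark coverage positions are taken as 1-based
(the documented convention for the ``.cov`` output of the methylation
extractor); bedGraph starts are 0-based half-open and converted to
1-based on read. BED exports are 0-based half-open.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CountTable,
    DMResult,
    GroupAssignment,
    MethylMatrix,
    Signature,
    site_key,
)

__all__ = [
    "read_bismark_cov",
    "merge_samples",
    "read_counts",
    "write_counts",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_signature",
    "read_signature",
    "read_external_dm_table",
]

_COMMENT = "#"


def _open_text(path) -> _io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bismark_cov(
    path,
    sample: str | None = None,
    dialect: str = "bismark",
    collapse_strand: bool = False,
) -> CountTable:
    """Read a single-sample Bismark coverage file into a CountTable.

    Columns: chrom, start, end, %methylation, count_methylated,
    count_unmethylated. The percent column is ignored in favour of the
    raw counts (coverage = methylated + unmethylated). ``dialect`` is
    ``"bismark"`` (1-based start, the .cov convention) or ``"bedgraph"``
    (0-based start). ``collapse_strand`` keys sites by (chrom, pos)
    regardless of strand; the default keeps input keys unchanged.
    """
    if dialect not in ("bismark", "bedgraph"):
        raise ValueError(f"unknown dialect {dialect!r}")
    offset = 0 if dialect == "bismark" else 1
    path = Path(path)
    if sample is None:
        sample = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    covs: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(_COMMENT) or line.startswith("track"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 fields "
                    f"(chrom start end %meth count_meth count_unmeth), got {len(fields)}"
                )
            chrom, start, _end, _pct, m, u = fields[:6]
            try:
                start_i = int(start)
                m_i = int(m)
                u_i = int(u)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field ({exc})") from None
            if m_i < 0 or u_i < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            chroms.append(chrom)
            poss.append(start_i + offset)
            meths.append(m_i)
            covs.append(m_i + u_i)
    keys = [site_key(c, p) for c, p in zip(chroms, poss)]
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "strand": "."}, index=pd.Index(keys, name="site"))
    if sites.index.has_duplicates:
        if collapse_strand:
            # adjacent strands of a CpG collapse onto one key: sum counts
            df = pd.DataFrame({"meth": meths, "cov": covs}, index=sites.index)
            agg = df.groupby(level=0, sort=False).sum()
            sites = sites[~sites.index.duplicated()]
            agg = agg.loc[sites.index]
            meths = agg["meth"].to_list()
            covs = agg["cov"].to_list()
        else:
            dup = sites.index[sites.index.duplicated()][0]
            raise ValueError(f"{path}: duplicate site {dup}")
    table = CountTable(
        sites,
        [sample],
        np.asarray(meths, dtype=np.int64)[:, None],
        np.asarray(covs, dtype=np.int64)[:, None],
    )
    return table.sorted_by_position()


def merge_samples(tables: Sequence[CountTable]) -> CountTable:
    """Outer-join single- or multi-sample count tables over the union of
    sites. Sites absent from a sample get meth=0, cov=0 (missing). Output
    site order is (chrom, pos)."""
    if not tables:
        raise ValueError("need at least one table")
    names: list[str] = []
    for t in tables:
        names.extend(t.samples)
    if len(names) != len(set(names)):
        raise ValueError("duplicate sample names across tables")
    site_frames = [t.sites for t in tables]
    all_sites = pd.concat(site_frames)
    all_sites = all_sites[~all_sites.index.duplicated()]
    order = np.lexsort((all_sites["pos"].to_numpy(), all_sites["chrom"].to_numpy()))
    all_sites = all_sites.iloc[order]
    n, m = len(all_sites), len(names)
    meth = np.zeros((n, m), dtype=np.int64)
    cov = np.zeros((n, m), dtype=np.int64)
    col = 0
    for t in tables:
        idx = all_sites.index.get_indexer(t.site_keys)
        for j in range(t.n_samples):
            meth[idx, col] = t.meth[:, j]
            cov[idx, col] = t.cov[:, j]
            col += 1
    return CountTable(all_sites, names, meth, cov)


# -- wide TSV count tables ---------------------------------------------------

def write_counts(table: CountTable, path, header_lines: Iterable[str] = ()) -> None:
    """Write a CountTable as TSV: chrom, pos, strand, then meth_<sample>
    and cov_<sample> column pairs."""
    df = table.sites.copy()
    for j, s in enumerate(table.samples):
        df[f"meth_{s}"] = table.meth[:, j]
        df[f"cov_{s}"] = table.cov[:, j]
    with open(path, "wt") as fh:
        for line in header_lines:
            fh.write(f"{_COMMENT} {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts(path) -> CountTable:
    df = pd.read_csv(path, sep="\t", comment=_COMMENT)
    required = {"chrom", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: count table needs columns {sorted(required)}")
    samples = [c.removeprefix("meth_") for c in df.columns if c.startswith("meth_")]
    for s in samples:
        if f"cov_{s}" not in df.columns:
            raise ValueError(f"{path}: missing cov_{s} column")
    keys = [site_key(c, p) for c, p in zip(df["chrom"], df["pos"])]
    sites = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str).to_list(),
            "pos": df["pos"].astype(int).to_list(),
            "strand": df["strand"].astype(str).to_list() if "strand" in df.columns else ".",
        },
        index=pd.Index(keys, name="site"),
    )
    meth = df[[f"meth_{s}" for s in samples]].to_numpy(dtype=np.int64)
    cov = df[[f"cov_{s}" for s in samples]].to_numpy(dtype=np.int64)
    return CountTable(sites, samples, meth, cov)


# -- beta matrices -----------------------------------------------------------

def read_beta_matrix(path) -> MethylMatrix:
    """TSV with a header row of sample names; first column is the site
    identifier. Empty cells / NA are missing."""
    df = pd.read_csv(path, sep="\t", comment=_COMMENT, index_col=0)
    return MethylMatrix(df)


def write_beta_matrix(matrix: MethylMatrix, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "wt") as fh:
        for line in header_lines:
            fh.write(f"{_COMMENT} {line}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="site")


# -- sample sheets -----------------------------------------------------------

def read_sample_sheet(path, samples: Sequence[str] | None = None) -> GroupAssignment:
    """TSV with columns ``sample`` and ``group``. If ``samples`` is given,
    every listed sample must appear in the sheet and unknown sheet entries
    raise."""
    df = pd.read_csv(path, sep="\t", comment=_COMMENT)
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(f"{path}: sample sheet needs 'sample' and 'group' columns")
    mapping = dict(zip(df["sample"].astype(str), df["group"].astype(str)))
    if len(mapping) != len(df):
        raise ValueError(f"{path}: duplicate sample entries")
    if samples is not None:
        unknown = sorted(set(mapping) - set(samples))
        if unknown:
            raise ValueError(f"{path}: samples in sheet but not in data: {unknown[:5]}")
        absent = sorted(set(samples) - set(mapping))
        if absent:
            raise ValueError(f"{path}: samples without group label: {absent[:5]}")
    return GroupAssignment(mapping)


def write_sample_sheet(groups: GroupAssignment, path) -> None:
    pd.DataFrame(
        {"sample": list(groups.mapping), "group": list(groups.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# -- signatures --------------------------------------------------------------

def write_signature(sig: Signature, path, format: str = "tsv", header_lines: Iterable[str] = ()) -> None:
    """Write a signature as TSV (site, score, diff, direction; row order =
    signature order) or BED (0-based half-open single-base intervals;
    requires ``chrom:pos`` site keys)."""
    if format == "tsv":
        with open(path, "wt") as fh:
            for line in header_lines:
                fh.write(f"{_COMMENT} {line}\n")
            sig.table.to_csv(fh, sep="\t", index_label="site")
    elif format == "bed":
        with open(path, "wt") as fh:
            for i, key in enumerate(sig.sites):
                parts = key.split(":")
                if len(parts) < 2:
                    raise ValueError(f"site key {key!r} is not chrom:pos; cannot export BED")
                chrom, pos = parts[0], int(parts[1])
                score = sig.table["score"].iloc[i] if "score" in sig.table.columns else "."
                fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{key}\t{score}\n")
    else:
        raise ValueError(f"unknown signature format {format!r}")


def read_signature(path) -> Signature:
    df = pd.read_csv(path, sep="\t", comment=_COMMENT, index_col=0)
    df.index = df.index.astype(str)
    return Signature(df)


# -- external DM result adapter ---------------------------------------------

def read_external_dm_table(
    path,
    columns: Mapping[str, str],
    method: str = "external",
    group1: str = "g1",
    group2: str = "g2",
    sep: str = "\t",
) -> DMResult:
    """Adapt a per-site result table from an external DM tool.

    ``columns`` maps internal names to the file's column names; ``site``
    plus at least one of ``p`` / ``p_adj`` / ``posterior`` are required.
    Optional: ``diff``, ``mean_g1``, ``mean_g2``, ``statistic``. A missing
    adjusted-p column is filled by Benjamini-Hochberg adjustment of the
    raw p-values. Posterior-based tools (HMM-DM style) supply
    ``posterior``; downstream signature building then sorts descending on
    it.
    """
    if "site" not in columns:
        raise ValueError("column map must name the site identifier column")
    score_cols = [k for k in ("p", "p_adj", "posterior") if k in columns]
    if not score_cols:
        raise ValueError("no usable score column: need one of p, p_adj, posterior")
    df = pd.read_csv(path, sep=sep, comment=_COMMENT)
    for internal, external in columns.items():
        if external not in df.columns:
            raise ValueError(f"{path}: column {external!r} (for {internal!r}) not found")
    out = pd.DataFrame(index=pd.Index(df[columns["site"]].astype(str), name="site"))
    for internal in ("statistic", "p", "p_adj", "posterior", "mean_g1", "mean_g2", "diff"):
        if internal in columns:
            out[internal] = df[columns[internal]].to_numpy(dtype=float)
    if "p" in out.columns and "p_adj" not in out.columns:
        from .dm import adjust_pvalues

        out["p_adj"] = adjust_pvalues(out["p"].to_numpy())
    return DMResult(out, group1=group1, group2=group2, method=method)
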
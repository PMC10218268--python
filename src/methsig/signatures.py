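"""Turn per-site DM test results into ordered methylation signatures.

A signature is the ordered list of differentially methylated sites a
test declares significant: adjusted p strictly below ``alpha`` (or
posterior strictly above a threshold for posterior-based tools) and
absolute group methylation difference at or above ``min_abs_diff``.
Sites are sorted by adjusted p ascending (posterior descending), with
ties broken lexicographically by site key so top-N subsets are stable
across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DMResult, Signature

__all__ = ["build_signature", "top_n"]


def build_signature(
    dm: DMResult,
    alpha: float = 0.05,
    min_abs_diff: float = 0.15,
    sort: str = "adjusted_p",
    posterior_threshold: float = 0.95,
) -> Signature:
    """Select and order significant sites from a DM result.

    ``sort`` is ``"adjusted_p"`` (include adjusted p < alpha, ascending
    order) or ``"posterior"`` (include posterior > threshold, descending
    order). In both cases sites with undefined scores or with
    ``|diff| < min_abs_diff`` are excluded. An empty signature is a
    legitimate outcome and keeps its provenance.
    """
    t = dm.table
    if sort == "adjusted_p":
        if "p_adj" not in t.columns:
            raise ValueError("DM result has no adjusted p column")
        score = t["p_adj"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            keep = ~np.isnan(score) & (score < alpha)
        ascending = True
    elif sort == "posterior":
        if "posterior" not in t.columns:
            raise ValueError("DM result has no posterior column")
        score = t["posterior"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            keep = ~np.isnan(score) & (score > posterior_threshold)
        ascending = False
    else:
        raise ValueError(f"unknown sort {sort!r}")

    if "diff" in t.columns:
        diff = t["diff"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            keep &= ~np.isnan(diff) & (np.abs(diff) >= min_abs_diff)
    else:
        diff = np.full(len(t), np.nan)

    sel = pd.DataFrame(
        {"score": score[keep], "diff": diff[keep]},
        index=t.index[keep],
    )
    sel["direction"] = np.where(
        np.isnan(sel["diff"]), "na", np.where(sel["diff"] > 0, "hyper", "hypo")
    )
    # deterministic order: score, then site key for ties
    order = np.lexsort((sel.index.to_numpy(), sel["score"].to_numpy() * (1 if ascending else -1)))
    sel = sel.iloc[order]
    provenance = {
        "method": dm.method,
        "group1": dm.group1,
        "group2": dm.group2,
        "alpha": alpha,
        "min_abs_diff": min_abs_diff,
        "sort": sort,
    }
    if sort == "posterior":
        provenance["posterior_threshold"] = posterior_threshold
    return Signature(sel, provenance=provenance)


def top_n(sig: Signature, n: int) -> Signature:
    """First ``min(n, len)`` sites in signature order."""
    if n < 0:
        raise ValueError("n must be non-negative")
    prov = dict(sig.provenance)
    prov["subset"] = n
    return Signature(sig.table.iloc[: min(n, len(sig))].copy(), provenance=prov)
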
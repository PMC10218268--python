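"""Two-group methylation data simulators with known ground truth.

The count simulator emulates reduced-representation bisulfite data:
CpG sites clustered into island-like regions plus scattered background
sites, negative-binomial sequencing depth, beta-binomial biological
variability, and a known methylation difference spiked into a chosen
number of regions of the case group (half hypermethylated, half
hypomethylated by default). The array simulator produces the analogous
site x sample beta-value matrix with shifted probes.

All generation is reproducible from the config seed; identical configs
give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import CountTable, GroupAssignment, MethylMatrix, Signature, site_key

__all__ = [
    "SimulationConfig",
    "BetaArrayConfig",
    "SimulationTruth",
    "simulate_spikein_counts",
    "simulate_null_counts",
    "simulate_beta_matrix",
    "make_mixed_signature",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the RRBS-like spike-in simulator.

    Defaults follow the benchmark's first simulation design: 16 case and
    16 control samples, 300 spiked CpG islands split evenly between
    hyper- and hypomethylation, and a target group difference ``delta``
    drawn from {0.1, 0.15, 0.2, 0.3} in the benchmark grid. Coverage is
    negative-binomial (mean 30, dispersion 0.3) and methylated counts
    are beta-binomial with biological dispersion ``phi`` = 0.05.
    Baseline levels are bimodal: island sites low (Beta(2, 8)),
    background sites high (Beta(8, 2)); hypo-spiked regions start from
    the high mode so the downward shift is observable.
    """

    n_case: int = 16
    n_control: int = 16
    n_regions: int = 300
    frac_hyper: float = 0.5
    delta: float = 0.2
    n_null_regions: int = 300
    n_background: int = 2000
    sites_per_region_mean: float = 15.0
    sites_per_region_min: int = 3
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.3
    phi: float = 0.05
    baseline_low: tuple[float, float] = (2.0, 8.0)
    baseline_high: tuple[float, float] = (8.0, 2.0)
    chrom: str = "chrS"
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta < 1.0):
            raise ValueError("delta must be in [0, 1)")
        if not (0.0 <= self.frac_hyper <= 1.0):
            raise ValueError("frac_hyper must be in [0, 1]")
        if self.n_regions < 0:
            raise ValueError("n_regions must be non-negative")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least two samples per group")
        if not (0.0 <= self.phi < 1.0):
            raise ValueError("phi must be in [0, 1)")


@dataclass(frozen=True)
class BetaArrayConfig:
    """Parameters of the microarray-like beta-matrix simulator.

    ``concentration`` is the Beta precision (alpha + beta) of per-sample
    beta values around the site mean; 60 gives an sd of about 0.05 at a
    mean of 0.2, in line with well-behaved array probes.
    """

    n_case: int = 8
    n_control: int = 8
    n_sites: int = 2000
    n_dmp: int = 100
    frac_hyper: float = 0.5
    delta: float = 0.2
    concentration: float = 60.0
    baseline_low: tuple[float, float] = (2.0, 8.0)
    baseline_high: tuple[float, float] = (8.0, 2.0)
    frac_low: float = 0.5
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta < 1.0):
            raise ValueError("delta must be in [0, 1)")
        if self.n_dmp > self.n_sites:
            raise ValueError("n_dmp cannot exceed n_sites")


@dataclass
class SimulationTruth:
    """Ground truth of a spike-in simulation.

    ``regions`` has one row per spiked region: region id, direction
    (hyper/hypo), nominal delta and the mean effective delta after
    clipping means into [0, 1]. ``true_sites`` are the spiked site keys;
    ``universe`` is every simulated site key.
    """

    true_sites: pd.Index
    regions: pd.DataFrame
    universe: pd.Index

    def __post_init__(self) -> None:
        if len(pd.Index(self.true_sites).difference(self.universe)):
            raise ValueError("truth sites must be a subset of the universe")

    @property
    def n_true(self) -> int:
        return len(self.true_sites)


def _region_site_counts(rng: np.random.Generator, n_regions: int, cfg: SimulationConfig) -> np.ndarray:
    if n_regions == 0:
        return np.zeros(0, dtype=np.int64)
    lam = max(cfg.sites_per_region_mean - cfg.sites_per_region_min, 0.0)
    return cfg.sites_per_region_min + rng.poisson(lam, size=n_regions)


def _beta_binomial_counts(
    rng: np.random.Generator, cov: np.ndarray, mean: np.ndarray, phi: float
) -> np.ndarray:
    """Beta-binomial draws: p ~ Beta with mean ``mean`` and dispersion
    ``phi`` (intra-class correlation), then Binomial(cov, p). phi = 0
    degenerates to pure binomial. Means exactly 0 or 1 give deterministic
    counts."""
    mean = np.broadcast_to(mean, cov.shape)
    if phi <= 0:
        return rng.binomial(cov, mean)
    conc = (1.0 - phi) / phi
    a = np.clip(mean * conc, 1e-12, None)
    b = np.clip((1.0 - mean) * conc, 1e-12, None)
    p = rng.beta(a, b)
    p = np.where(mean <= 0, 0.0, np.where(mean >= 1, 1.0, p))
    return rng.binomial(cov, p)


def _nb_coverage(rng: np.random.Generator, shape: tuple[int, int], mean: float, dispersion: float) -> np.ndarray:
    """Negative-binomial coverage with var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=shape)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=shape)


def simulate_spikein_counts(
    config: SimulationConfig,
) -> tuple[CountTable, GroupAssignment, SimulationTruth]:
    """Simulate a two-group RRBS-like count table with spiked regions.

    Case-group means of spiked sites are ``clip(p0 +/- delta, 0, 1)``
    with the sign set per region; control means stay at baseline. Every
    spiked site is recorded in the truth, along with each region's
    effective (post-clipping) delta.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_hyper = int(round(cfg.frac_hyper * cfg.n_regions))
    directions = np.array(["hyper"] * n_hyper + ["hypo"] * (cfg.n_regions - n_hyper))

    spike_sizes = _region_site_counts(rng, cfg.n_regions, cfg)
    null_sizes = _region_site_counts(rng, cfg.n_null_regions, cfg)

    # site layout on one synthetic chromosome: regions spaced 10 kb apart,
    # CpGs 50 bp apart within a region, background sites on a separate arm
    chroms: list[str] = []
    positions: list[int] = []
    region_ids: list[int] = []
    pos = 1000
    for rid, size in enumerate(np.concatenate([spike_sizes, null_sizes])):
        for k in range(int(size)):
            positions.append(pos + 50 * k)
            region_ids.append(rid)
        pos += 10_000
    bg_start = pos + 100_000
    for k in range(cfg.n_background):
        positions.append(bg_start + 200 * k)
        region_ids.append(-1)
    chroms = [cfg.chrom] * len(positions)
    region_ids = np.asarray(region_ids)
    n_sites = len(positions)
    keys = pd.Index([site_key(c, p) for c, p in zip(chroms, positions)], name="site")
    sites = pd.DataFrame({"chrom": chroms, "pos": positions, "strand": "."}, index=keys)
    sites["region"] = region_ids

    # baseline means: spiked hyper + null-island + nothing -> low mode;
    # spiked hypo + background -> high mode
    low_a, low_b = cfg.baseline_low
    high_a, high_b = cfg.baseline_high
    baseline = np.empty(n_sites)
    spiked_region = (region_ids >= 0) & (region_ids < cfg.n_regions)
    is_hypo_region = np.zeros(n_sites, dtype=bool)
    if cfg.n_regions:
        dir_is_hypo = directions == "hypo"
        safe_ids = np.where(spiked_region, region_ids, 0)
        is_hypo_region = spiked_region & dir_is_hypo[safe_ids]
    high_mode = is_hypo_region | (region_ids == -1)
    baseline[~high_mode] = rng.beta(low_a, low_b, size=(~high_mode).sum())
    baseline[high_mode] = rng.beta(high_a, high_b, size=high_mode.sum())

    case_mean = baseline.copy()
    if cfg.n_regions:
        sgn = np.where(is_hypo_region, -1.0, 1.0)
        case_mean = np.where(spiked_region, np.clip(baseline + sgn * cfg.delta, 0.0, 1.0), baseline)

    samples = [f"case_{i + 1}" for i in range(cfg.n_case)] + [
        f"ctrl_{i + 1}" for i in range(cfg.n_control)
    ]
    groups = GroupAssignment(
        {s: ("case" if s.startswith("case") else "control") for s in samples}
    )
    n_samp = len(samples)
    cov = _nb_coverage(rng, (n_sites, n_samp), cfg.coverage_mean, cfg.coverage_dispersion)
    means = np.column_stack(
        [case_mean] * cfg.n_case + [baseline] * cfg.n_control
    )
    meth = _beta_binomial_counts(rng, cov, means, cfg.phi)
    table = CountTable(sites, samples, meth, cov)

    if cfg.n_regions:
        eff = np.abs(case_mean - baseline)
        reg_rows = []
        for rid in range(cfg.n_regions):
            mask = region_ids == rid
            reg_rows.append(
                {
                    "region": rid,
                    "direction": directions[rid],
                    "delta": cfg.delta,
                    "effective_delta": float(eff[mask].mean()) if mask.any() else np.nan,
                    "n_sites": int(mask.sum()),
                }
            )
        regions = pd.DataFrame(reg_rows).set_index("region")
        if cfg.delta > 0 and np.all(eff[spiked_region] <= 1e-12):
            warnings.warn(
                "all spiked sites clipped to the boundary in both groups; effective delta is zero",
                RuntimeWarning,
            )
    else:
        regions = pd.DataFrame(
            columns=["direction", "delta", "effective_delta", "n_sites"]
        )
    truth = SimulationTruth(
        true_sites=keys[spiked_region],
        regions=regions,
        universe=keys,
    )
    return table, groups, truth


def simulate_null_counts(
    config: SimulationConfig,
) -> tuple[CountTable, GroupAssignment, SimulationTruth]:
    """Spike-free companion of :func:`simulate_spikein_counts`: identical
    generative model with no regions spiked, so the truth is empty."""
    return simulate_spikein_counts(replace(config, n_regions=0, delta=0.0))


def simulate_beta_matrix(
    config: BetaArrayConfig,
) -> tuple[MethylMatrix, GroupAssignment, SimulationTruth]:
    """Simulate a microarray-like beta matrix with shifted DMPs.

    Site means come from a two-mode Beta mixture; per-sample values are
    Beta-distributed around the site mean with precision
    ``concentration``. DMP case means are ``clip(mu +/- delta, eps,
    1-eps)`` with half the probes shifted up, half down (hypo probes
    drawn from the high mode so the shift is feasible).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    keys = pd.Index([f"probe_{i:06d}" for i in range(n)], name="site")

    n_hyper = int(round(cfg.frac_hyper * cfg.n_dmp))
    dmp_idx = np.arange(cfg.n_dmp)  # deterministic placement; values are random
    is_dmp = np.zeros(n, dtype=bool)
    is_dmp[dmp_idx] = True
    hypo = np.zeros(n, dtype=bool)
    hypo[dmp_idx[n_hyper:]] = True

    low_mode = rng.random(n) < cfg.frac_low
    low_mode[dmp_idx[:n_hyper]] = True
    low_mode[dmp_idx[n_hyper:]] = False
    mu = np.where(
        low_mode,
        rng.beta(*cfg.baseline_low, size=n),
        rng.beta(*cfg.baseline_high, size=n),
    )
    case_mu = mu.copy()
    sgn = np.where(hypo, -1.0, 1.0)
    eps = 1e-3  # keep Beta parameters proper
    case_mu = np.where(is_dmp, np.clip(mu + sgn * cfg.delta, eps, 1 - eps), mu)

    samples = [f"case_{i + 1}" for i in range(cfg.n_case)] + [
        f"ctrl_{i + 1}" for i in range(cfg.n_control)
    ]
    groups = GroupAssignment({s: ("case" if s.startswith("case") else "control") for s in samples})
    means = np.column_stack([case_mu] * cfg.n_case + [mu] * cfg.n_control)
    a = means * cfg.concentration
    b = (1.0 - means) * cfg.concentration
    values = rng.beta(np.clip(a, 1e-6, None), np.clip(b, 1e-6, None))
    matrix = MethylMatrix(pd.DataFrame(values, index=keys, columns=samples))

    regions = pd.DataFrame(
        {
            "direction": np.where(hypo[dmp_idx], "hypo", "hyper"),
            "delta": cfg.delta,
            "effective_delta": np.abs(case_mu - mu)[dmp_idx],
            "n_sites": 1,
        },
        index=pd.RangeIndex(cfg.n_dmp, name="region"),
    )
    truth = SimulationTruth(true_sites=keys[is_dmp], regions=regions, universe=keys)
    return matrix, groups, truth


def make_mixed_signature(
    truth: SimulationTruth,
    universe: Iterable[str] | None,
    length: int,
    tp_fraction: float,
    seed: int | np.random.Generator | None = None,
) -> Signature:
    """Random signature with a controlled true-positive content.

    Exactly ``round(tp_fraction * length)`` sites are sampled without
    replacement from the truth and the remainder from the non-truth part
    of the universe (defaults to the truth's own universe).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uni = pd.Index(universe) if universe is not None else truth.universe
    if length > len(uni):
        raise ValueError(f"length {length} exceeds universe size {len(uni)}")
    if not (0.0 <= tp_fraction <= 1.0):
        raise ValueError("tp_fraction must be in [0, 1]")
    n_tp = int(round(tp_fraction * length))
    n_fp = length - n_tp
    pool_tp = uni.intersection(truth.true_sites)
    pool_fp = uni.difference(truth.true_sites)
    if n_tp > len(pool_tp) or n_fp > len(pool_fp):
        raise ValueError(
            f"infeasible composition: need {n_tp} truth / {n_fp} non-truth sites, "
            f"pools have {len(pool_tp)} / {len(pool_fp)}"
        )
    empty = np.array([], dtype=np.intp)
    picked_tp = rng.choice(len(pool_tp), size=n_tp, replace=False) if n_tp else empty
    picked_fp = rng.choice(len(pool_fp), size=n_fp, replace=False) if n_fp else empty
    sites = list(pool_tp[np.sort(picked_tp)]) + list(pool_fp[np.sort(picked_fp)])
    table = pd.DataFrame(
        {"score": np.nan, "diff": np.nan, "direction": "na"},
        index=pd.Index(sites, name="site"),
    )
    return Signature(
        table,
        provenance={
            "method": "mixed_synthetic",
            "tp_fraction": tp_fraction,
            "length": length,
            "n_true": n_tp,
        },
    )
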
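import numpy as np
import pandas as pd
import pytest

from methsig import CountTable, GroupAssignment, MethylMatrix


def make_count_table(meth, cov, samples=None, chrom="chr1"):
    """CountTable from plain 2-D arrays, sites at consecutive positions."""
    meth = np.asarray(meth)
    cov = np.asarray(cov)
    n_sites, n_samples = cov.shape
    if samples is None:
        samples = [f"s{j + 1}" for j in range(n_samples)]
    pos = np.arange(1, n_sites + 1) * 100
    keys = [f"{chrom}:{p}" for p in pos]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "strand": "."},
        index=pd.Index(keys, name="site"),
    )
    return CountTable(sites, samples, meth, cov)


def two_group(n1, n2, g1="case", g2="control", prefix1="a", prefix2="b"):
    mapping = {f"{prefix1}{i + 1}": g1 for i in range(n1)}
    mapping.update({f"{prefix2}{i + 1}": g2 for i in range(n2)})
    return GroupAssignment(mapping)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4-sample, 6-site methylation matrix with clean group structure."""
    vals = pd.DataFrame(
        {
            "a1": [0.1, 0.2, 0.15, 0.8, 0.9, 0.5],
            "a2": [0.12, 0.18, 0.17, 0.82, 0.88, 0.52],
            "b1": [0.7, 0.75, 0.72, 0.2, 0.3, 0.48],
            "b2": [0.68, 0.77, 0.70, 0.22, 0.28, 0.51],
        },
        index=pd.Index([f"chr1:{100 * (i + 1)}" for i in range(6)], name="site"),
    )
    return MethylMatrix(vals)


@pytest.fixture
def small_groups():
    return GroupAssignment({"a1": "case", "a2": "case", "b1": "control", "b2": "control"})
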
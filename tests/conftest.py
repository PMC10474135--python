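"""Shared fixtures: small simulated datasets and hand-built sumstats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleiocond import SimParams, SumStats, simulate_pair
from pleiocond.simulate import analytic_panel, simulate_ld_panel


def make_sumstats(rows, trait="t"):
    """Build a SumStats from (snp, chrom, pos, a1, a2, z) tuples."""
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2", "z"])
    df["p"] = 2.0 * stats.norm.sf(np.abs(df["z"]))
    df.loc[df["z"] == 0, "p"] = 1.0
    df["n"] = 1000.0
    return SumStats(df, trait=trait)


def constant_conditional(s):
    """A degenerate conditional trait (z = 0 everywhere): conditioning on it
    reproduces the unconditional analysis through the same machinery."""
    df = s.df.copy()
    df["z"] = 0.0
    df["p"] = 1.0
    return SumStats(df, trait="const")


def dilate_mask(mask, lags):
    """True within +-lags of any set position (LD neighbourhood truth)."""
    out = np.zeros_like(mask)
    idx = np.flatnonzero(mask)
    for k in range(-lags, lags + 1):
        j = idx + k
        j = j[(j >= 0) & (j < mask.size)]
        out[j] = True
    return out


@pytest.fixture(scope="session")
def small_params():
    return SimParams(
        m=5000, n_chrom=2, block_size=50, seed=11,
        pi11=0.004, pi10=0.002, pi01=0.002, rho_shared=0.8,
    )


@pytest.fixture(scope="session")
def small_pair(small_params):
    return simulate_pair(small_params)


@pytest.fixture(scope="session")
def small_panel(small_params):
    return analytic_panel(small_params)


@pytest.fixture(scope="session")
def genotype_panel(small_params):
    return simulate_ld_panel(small_params, n_ref=400)


def realized_architecture(truth, params):
    """Exact realized (h2_1, h2_2, gcov, rg) for one simulated replicate.

    The genetic variance with LD is beta' R beta, computed block-wise from
    the AR(1) correlation matrices; a replicate's estimand is its realized
    architecture, not the mixture expectation.
    """
    from scipy.linalg import toeplitz

    b1 = truth.df["beta1"].to_numpy()
    b2 = truth.df["beta2"].to_numpy()
    bs = params.block_size
    nb = params.m // bs
    r_block = params.r_per_snp().reshape(nb, bs)[:, 0]
    B1 = b1.reshape(nb, bs)
    B2 = b2.reshape(nb, bs)
    h1 = h2 = gc = 0.0
    for rho in np.unique(r_block):
        R = toeplitz(rho ** np.arange(bs))
        rows = r_block == rho
        h1 += np.einsum("ij,jk,ik->", B1[rows], R, B1[rows])
        h2 += np.einsum("ij,jk,ik->", B2[rows], R, B2[rows])
        gc += np.einsum("ij,jk,ik->", B1[rows], R, B2[rows])
    rg = gc / np.sqrt(h1 * h2) if h1 > 0 and h2 > 0 else np.nan
    return h1, h2, gc, rg
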
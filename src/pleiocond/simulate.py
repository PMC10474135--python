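"""Bivariate GWAS simulator with known causal architecture and block LD.

The generator draws two traits from a four-component causal mixture
(null / trait-1-only / trait-2-only / shared), with effects on the
standardized-genotype scale, AR(1) linkage disequilibrium within
independent blocks, and optional cross-trait noise coupling emulating
sample overlap. Marginal z-scores follow

    z_t = sqrt(n_t) * R @ beta_t + e_t,      Cov(e_t) = R,
    Cov(e_1, e_2) = rho_overlap * R,

where R is the block-diagonal LD correlation matrix. This reproduces the
LD-score-regression expectation E[z^2] = 1 + n * h2 * l / M with
h2 = pi_causal * M * sigma_sq, so heritability, genetic correlation and
FDR operating characteristics are all known in closed form.

The LD reference panel is simulated by a haplotype-copying Markov chain:
each haplotype allele copies its left neighbour with probability
``r_within`` and is otherwise drawn fresh, which yields exactly AR(1)
correlation r_within^d between dosages at lag d, for any allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import toeplitz

from .sumstats import SumStats

# ordered non-palindromic allele pairs assigned to simulated SNPs
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the bivariate causal-mixture simulation.

    m              total SNP count (must tile evenly into chromosomes and blocks)
    n1, n2         effective sample sizes per trait
    pi10/pi01/pi11 mixture fractions of trait-1-only, trait-2-only and shared
                   causal SNPs (the null fraction is 1 minus their sum)
    sigma*_sq      per-causal-SNP effect variance, standardized-genotype scale
                   (so h2_t = (pi_t-only + pi11) * m * sigma_t_sq)
    rho_shared     correlation of effect sizes within the shared component
    block_size     SNPs per LD block
    r_within       AR(1) dosage correlation between adjacent SNPs in a block
    rho_overlap    residual z-score correlation from sample overlap
    n_chrom        chromosomes to tile ("1".."n_chrom")
    spacing_bp     fixed distance between adjacent SNP positions
    maf            minor-allele frequency of panel haplotypes
    seed           base seed; identical seeds give bit-identical output
    """

    m: int = 100_000
    n1: float = 50_000.0
    n2: float = 50_000.0
    pi10: float = 0.003
    pi01: float = 0.003
    pi11: float = 0.002
    sigma1_sq: float = 3e-4
    sigma2_sq: float = 3e-4
    rho_shared: float = 0.8
    block_size: int = 50
    r_within: float | tuple = 0.9
    rho_overlap: float = 0.0
    n_chrom: int = 2
    spacing_bp: int = 10_000
    maf: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.pi10 + self.pi01 + self.pi11 > 1:
            raise ValueError("mixture fractions must sum to <= 1")
        if min(self.pi10, self.pi01, self.pi11) < 0:
            raise ValueError("mixture fractions must be >= 0")
        if self.sigma1_sq < 0 or self.sigma2_sq < 0:
            raise ValueError("effect variances must be >= 0")
        if not (-1 <= self.rho_shared <= 1 and -1 <= self.rho_overlap <= 1):
            raise ValueError("correlations must lie in [-1, 1]")
        rw = self.r_within if isinstance(self.r_within, (tuple, list)) else (self.r_within,)
        if any(not 0 <= r < 1 for r in rw):
            raise ValueError("r_within values must lie in [0, 1)")
        if isinstance(self.r_within, (tuple, list)) and len(rw) != self.n_chrom:
            raise ValueError("per-chromosome r_within needs n_chrom values")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.m % (self.n_chrom * self.block_size) != 0:
            raise ValueError(
                "m must be divisible by n_chrom * block_size for even tiling"
            )
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")

    @property
    def n_blocks(self) -> int:
        return self.m // self.block_size

    def r_per_chrom(self) -> np.ndarray:
        """Within-block AR(1) correlation for each chromosome.

        A scalar ``r_within`` applies genome-wide; a tuple gives each
        chromosome its own LD strength (heterogeneous LD spreads the LD
        scores, which is what makes LD score regression well conditioned).
        """
        if isinstance(self.r_within, (tuple, list)):
            return np.asarray(self.r_within, dtype=float)
        return np.full(self.n_chrom, float(self.r_within))

    def r_per_snp(self) -> np.ndarray:
        per_chrom = self.m // self.n_chrom
        return np.repeat(self.r_per_chrom(), per_chrom)

    def snp_table(self) -> pd.DataFrame:
        """SNP ids, coordinates and block assignment implied by the tiling."""
        m, per_chrom = self.m, self.m // self.n_chrom
        idx = np.arange(m)
        chrom = (idx // per_chrom + 1).astype(str)
        pos = (idx % per_chrom + 1) * self.spacing_bp
        block = idx // self.block_size
        snp = np.array([f"rs{i + 1}" for i in idx])
        return pd.DataFrame(
            {"snp": snp, "chrom": chrom, "pos": pos, "block_id": block}
        )


@dataclass
class TruthTable:
    """Per-SNP causal status and effects for both simulated traits."""

    df: pd.DataFrame  # snp, block_id, causal1, causal2, beta1, beta2
    params: SimParams

    @property
    def causal1(self) -> np.ndarray:
        return self.df["causal1"].to_numpy(bool)

    @property
    def causal2(self) -> np.ndarray:
        return self.df["causal2"].to_numpy(bool)

    @property
    def shared(self) -> np.ndarray:
        return self.causal1 & self.causal2


@dataclass
class LdPanel:
    """SNP coordinates plus pairwise LD, from genotypes or an AR(1) model.

    Two backends: a dosage matrix (``genotypes``, individuals x SNPs) whose
    squared Pearson correlations give empirical r2, or an analytic AR(1)
    model (``ar1_r`` set) where r2(i, j) = ar1_r^(2|i-j|) within a block and
    0 across blocks.
    """

    snp: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    block_id: np.ndarray
    genotypes: np.ndarray | None = None
    ar1_r: float | np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.genotypes is None and self.ar1_r is None:
            raise ValueError("panel needs genotypes or an analytic ar1_r")
        if self.ar1_r is not None and np.ndim(self.ar1_r) > 0:
            self.ar1_r = np.asarray(self.ar1_r, dtype=float)
            if self.ar1_r.shape[0] != self.snp.shape[0]:
                raise ValueError("per-SNP ar1_r must match the SNP count")
        self._index = {s: i for i, s in enumerate(self.snp)}

    def _r_of(self, idx: np.ndarray) -> np.ndarray:
        """AR(1) parameter per queried SNP (constant within a block)."""
        if np.ndim(self.ar1_r) == 0:
            return np.full(idx.size, float(self.ar1_r))
        return self.ar1_r[idx]

    def __len__(self) -> int:
        return len(self.snp)

    @property
    def n_ref(self) -> int | None:
        return None if self.genotypes is None else self.genotypes.shape[0]

    def indices(self, snps) -> np.ndarray:
        try:
            return np.array([self._index[s] for s in snps], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"SNP {e.args[0]!r} not in LD panel") from None

    def r2_matrix(self, snps) -> np.ndarray:
        """Symmetric r2 table for the given SNP ids (diagonal exactly 1)."""
        idx = self.indices(snps)
        if self.genotypes is not None:
            g = self.genotypes[:, idx].astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.corrcoef(g, rowvar=False)
            r = np.atleast_2d(r)
            # monomorphic columns yield NaN: treat as uninformative (r2 = 0)
            r2 = np.nan_to_num(r * r, nan=0.0)
        else:
            lag = np.abs(idx[:, None] - idx[None, :])
            same = self.block_id[idx][:, None] == self.block_id[idx][None, :]
            r = self._r_of(idx)[:, None]  # same-block pairs share one r
            with np.errstate(divide="ignore"):
                r2 = np.where(same, r ** (2.0 * lag), 0.0)
        np.fill_diagonal(r2, 1.0)
        return r2

    def max_lag(self, r2_threshold: float) -> int:
        """Largest index lag whose expected r2 still reaches the threshold."""
        if self.ar1_r is None:
            raise ValueError("max_lag requires an analytic AR(1) panel")
        r = float(np.max(self.ar1_r))
        if r == 0:
            return 0
        d = int(np.floor(np.log(r2_threshold) / (2.0 * np.log(r))))
        return max(d, 0)


def simulate_ld_panel(params: SimParams, n_ref: int = 500) -> LdPanel:
    """Simulate a genotype reference panel matching ``params``'s LD structure.

    Each of ``n_ref`` individuals carries two haplotypes generated by the
    copying chain; dosages are their sum (0/1/2). Expected dosage
    correlation between SNPs at lag d within a block is r_within^d.
    """
    if n_ref < 50:
        raise ValueError("n_ref must be >= 50 for usable empirical r2")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    tab = params.snp_table()
    m, bs = params.m, params.block_size
    nb = m // bs
    r_block = params.r_per_snp().reshape(nb, bs)[:, 0]  # one r per block
    dosage = np.zeros((n_ref, m), dtype=np.int8)
    for _hap in range(2):
        fresh = rng.random((n_ref, nb, bs)) < params.maf
        copy = rng.random((n_ref, nb, bs)) < r_block[None, :, None]
        h = np.empty((n_ref, nb, bs), dtype=bool)
        h[:, :, 0] = fresh[:, :, 0]
        for j in range(1, bs):
            h[:, :, j] = np.where(copy[:, :, j], h[:, :, j - 1], fresh[:, :, j])
        dosage += h.reshape(n_ref, m)
    return LdPanel(
        snp=tab["snp"].to_numpy(),
        chrom=tab["chrom"].to_numpy(),
        pos=tab["pos"].to_numpy(),
        block_id=tab["block_id"].to_numpy(),
        genotypes=dosage,
        ar1_r=params.r_per_snp(),
    )


def analytic_panel(params: SimParams) -> LdPanel:
    """The exact AR(1) LD model as a panel (no genotype sampling noise)."""
    tab = params.snp_table()
    return LdPanel(
        snp=tab["snp"].to_numpy(),
        chrom=tab["chrom"].to_numpy(),
        pos=tab["pos"].to_numpy(),
        block_id=tab["block_id"].to_numpy(),
        ar1_r=params.r_per_snp(),
    )


def _ar1_color(w: np.ndarray, rho_block: np.ndarray, block_size: int) -> np.ndarray:
    """Color iid N(0,1) noise to stationary AR(1) within each block."""
    nb = w.shape[0] // block_size
    x = w.reshape(nb, block_size).copy()
    rho = rho_block
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, block_size):
        x[:, j] = rho * x[:, j - 1] + c * x[:, j]
    return x.reshape(-1)


def _ld_smooth(beta: np.ndarray, rho_block: np.ndarray, block_size: int) -> np.ndarray:
    """Apply the block AR(1) correlation matrix R to a vector of effects."""
    nb = beta.shape[0] // block_size
    bb = beta.reshape(nb, block_size)
    out = np.empty_like(bb)
    for rho in np.unique(rho_block):
        R = toeplitz(rho ** np.arange(block_size))
        rows = rho_block == rho
        out[rows] = bb[rows] @ R
    return out.reshape(-1)


def simulate_pair(params: SimParams) -> tuple[SumStats, SumStats, TruthTable]:
    """Draw one pair of GWAS summary statistics plus ground truth.

    Deterministic given ``params.seed``. The two traits are emitted with
    identical allele assignments (already harmonized).
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    m, bs = params.m, params.block_size
    tab = params.snp_table()

    # four-component causal assignment
    u = rng.random(m)
    c10 = u < params.pi10
    c01 = (u >= params.pi10) & (u < params.pi10 + params.pi01)
    c11 = (u >= params.pi10 + params.pi01) & (
        u < params.pi10 + params.pi01 + params.pi11
    )
    causal1 = c10 | c11
    causal2 = c01 | c11

    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    s1, s2 = np.sqrt(params.sigma1_sq), np.sqrt(params.sigma2_sq)
    beta1[c10] = s1 * rng.standard_normal(int(c10.sum()))
    beta2[c01] = s2 * rng.standard_normal(int(c01.sum()))
    k = int(c11.sum())
    if k:
        g = rng.standard_normal((k, 2))
        rho = params.rho_shared
        shared1 = g[:, 0]
        shared2 = rho * g[:, 0] + np.sqrt(1.0 - rho * rho) * g[:, 1]
        beta1[c11] = s1 * shared1
        beta2[c11] = s2 * shared2

    # correlated noise: Cov(e_t)=R, Cov(e1,e2)=rho_overlap*R
    wa = rng.standard_normal(m)
    wb = rng.standard_normal(m)
    ro = params.rho_overlap
    nb = m // bs
    r_block = params.r_per_snp().reshape(nb, bs)[:, 0]
    e1 = _ar1_color(wa, r_block, bs)
    e2 = _ar1_color(ro * wa + np.sqrt(1.0 - ro * ro) * wb, r_block, bs)

    z1 = np.sqrt(params.n1) * _ld_smooth(beta1, r_block, bs) + e1
    z2 = np.sqrt(params.n2) * _ld_smooth(beta2, r_block, bs) + e2

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    def _stats(z, n, trait):
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        return SumStats(
            pd.DataFrame(
                {
                    "snp": tab["snp"],
                    "chrom": tab["chrom"],
                    "pos": tab["pos"],
                    "a1": a1,
                    "a2": a2,
                    "z": z,
                    "p": p,
                    "n": float(n),
                }
            ),
            trait=trait,
        )

    truth = TruthTable(
        pd.DataFrame(
            {
                "snp": tab["snp"],
                "block_id": tab["block_id"],
                "causal1": causal1,
                "causal2": causal2,
                "beta1": beta1,
                "beta2": beta2,
            }
        ),
        params,
    )
    return _stats(z1, params.n1, "trait1"), _stats(z2, params.n2, "trait2"), truth
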
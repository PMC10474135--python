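"""SNP heritability and genetic correlation by LD score regression.

Univariate model:  E[z_j^2]      = 1 + N * h2 * l_j / M
Bivariate model:   E[z1_j z2_j]  = c  + sqrt(N1 N2) * gcov * l_j / M

where l_j is SNP j's LD score (sum of r2 with all panel SNPs in a window,
including itself), M the SNP count, and the free intercepts absorb
confounding and sample overlap. Genetic correlation is
rg = gcov / sqrt(h2_1 * h2_2). Standard errors come from a delete-one
block jackknife over contiguous genomic blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .simulate import LdPanel
from .sumstats import SumStats

logger = logging.getLogger(__name__)


@dataclass
class LdScores:
    """Per-SNP LD scores, aligned to a panel's SNP order."""

    snp: np.ndarray
    ell: np.ndarray
    M: int

    def align(self, s: SumStats) -> np.ndarray:
        index = {v: i for i, v in enumerate(self.snp)}
        idx = np.array([index[v] for v in s.snp], dtype=np.int64)
        return self.ell[idx]


@dataclass
class RgEstimate:
    """Genetic-correlation estimate with heritabilities and intercepts."""

    h2_1: float
    h2_2: float
    gcov: float
    rg: float
    se_rg: float
    intercept_1: float
    intercept_2: float
    intercept_biv: float
    defined: bool = True


def compute_ld_scores(panel: LdPanel, window_bp: int = 1_000_000) -> LdScores:
    """LD scores l_j = sum_k r2(j, k) over panel SNPs within the window.

    For an analytic AR(1) panel the within-block geometric sums are exact.
    For a genotype panel, empirical r2 within each LD block is summed after
    the small-sample bias adjustment r2_adj = r2 - (1 - r2)/(n_ref - 2);
    cross-block terms have zero expectation after adjustment and are
    skipped. Scores are floored at 1 (the self term).
    """
    m = len(panel)
    pos = panel.pos
    block_id = panel.block_id
    ell = np.ones(m)
    spacing = np.median(np.abs(np.diff(pos))) if m > 1 else 0
    if window_bp < spacing:
        logger.warning("window smaller than SNP spacing: all LD scores = 1")
        return LdScores(snp=panel.snp, ell=ell, M=m)

    for b in np.unique(block_id):
        idx = np.flatnonzero(block_id == b)
        bpos = pos[idx]
        within = np.abs(bpos[:, None] - bpos[None, :]) <= window_bp
        if panel.genotypes is None:
            lag = np.abs(np.arange(idx.size)[:, None] - np.arange(idx.size)[None, :])
            r_b = float(panel._r_of(idx[:1])[0])  # one AR(1) value per block
            r2 = r_b ** (2.0 * lag)
        else:
            g = panel.genotypes[:, idx].astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.corrcoef(g, rowvar=False)
            r2 = np.nan_to_num(np.atleast_2d(r) ** 2, nan=0.0)
            n_ref = panel.genotypes.shape[0]
            if n_ref > 2:
                r2 = r2 - (1.0 - r2) / (n_ref - 2)
            np.fill_diagonal(r2, 1.0)
        ell[idx] = (r2 * within).sum(axis=1)
    return LdScores(snp=panel.snp, ell=np.maximum(ell, 1.0), M=m)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    sxy = (w * (x - mx) * (y - my)).sum()
    slope = sxy / sxx
    return my - slope * mx, slope


def _jackknife_blocks(n: int, n_blocks: int) -> list[np.ndarray]:
    return [b for b in np.array_split(np.arange(n), n_blocks) if b.size]


def estimate_h2(
    s: SumStats, scores: LdScores, n_blocks: int = 20
) -> tuple[float, float, float]:
    """SNP heritability: WLS of z^2 on N*l/M with a free intercept.

    Weights are 1/l (a single-pass simplification of the canonical
    two-step heteroscedasticity weighting). Returns (h2, intercept,
    jackknife SE of h2) with the SE from ``n_blocks`` contiguous blocks.
    """
    if len(s) < n_blocks:
        raise ValueError("fewer SNPs than jackknife blocks")
    ell = scores.align(s)
    x = s.df["n"].to_numpy(float) * ell / scores.M
    y = s.z**2
    w = 1.0 / ell
    intercept, h2 = _wls(x, y, w)
    ests = []
    for blk in _jackknife_blocks(len(s), n_blocks):
        mask = np.ones(len(s), dtype=bool)
        mask[blk] = False
        ests.append(_wls(x[mask], y[mask], w[mask])[1])
    ests = np.asarray(ests)
    B = ests.size
    se = float(np.sqrt((B - 1) / B * ((ests - ests.mean()) ** 2).sum()))
    return float(h2), float(intercept), se


def estimate_rg(
    a: SumStats, b: SumStats, scores: LdScores, n_blocks: int = 20
) -> RgEstimate:
    """Cross-trait genetic correlation by bivariate LD score regression.

    Regresses z1*z2 on sqrt(N1*N2)*l/M with a free intercept (which
    absorbs sample-overlap-induced correlation), normalizes the genetic
    covariance by the two heritabilities, and jackknifes the whole
    pipeline over contiguous blocks for the SE of rg. rg is clipped to
    [-1, 1]; if either heritability estimate is non-positive the estimate
    is flagged undefined.
    """
    if len(a) != len(b) or not a.snp.equals(b.snp):
        raise ValueError("inputs must be harmonized to the same SNP order")
    if len(a) < n_blocks:
        raise ValueError("fewer SNPs than jackknife blocks")
    ell = scores.align(a)
    M = scores.M
    n1 = a.df["n"].to_numpy(float)
    n2 = b.df["n"].to_numpy(float)
    w = 1.0 / ell

    x1 = n1 * ell / M
    x2 = n2 * ell / M
    x12 = np.sqrt(n1 * n2) * ell / M
    y1, y2, y12 = a.z**2, b.z**2, a.z * b.z

    def _full(mask=None):
        if mask is None:
            mask = slice(None)
        i1, h2_1 = _wls(x1[mask], y1[mask], w[mask])
        i2, h2_2 = _wls(x2[mask], y2[mask], w[mask])
        ib, gcov = _wls(x12[mask], y12[mask], w[mask])
        if h2_1 > 0 and h2_2 > 0:
            rg = float(gcov / np.sqrt(h2_1 * h2_2))  # unclipped for jackknife
        else:
            rg = np.nan
        return h2_1, h2_2, gcov, rg, i1, i2, ib

    h2_1, h2_2, gcov, rg, i1, i2, ib = _full()
    defined = np.isfinite(rg)
    if not defined:
        logger.warning("rg undefined: non-positive heritability estimate")

    ests = []
    for blk in _jackknife_blocks(len(a), n_blocks):
        mask = np.ones(len(a), dtype=bool)
        mask[blk] = False
        ests.append(_full(mask)[3])
    ests = np.asarray([e for e in ests if np.isfinite(e)])
    if ests.size >= 2:
        B = ests.size
        se = float(np.sqrt((B - 1) / B * ((ests - ests.mean()) ** 2).sum()))
    else:
        se = float("nan")
    return RgEstimate(
        h2_1=float(h2_1),
        h2_2=float(h2_2),
        gcov=float(gcov),
        rg=float(np.clip(rg, -1.0, 1.0)) if defined else float("nan"),
        se_rg=se,
        intercept_1=float(i1),
        intercept_2=float(i2),
        intercept_biv=float(ib),
        defined=bool(defined),
    )
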
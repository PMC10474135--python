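"""Conditional and conjunctional FDR via an empirical 2D lookup grid.

The conditional FDR of a SNP for a primary trait given a conditional trait
is estimated as

    condFDR(p1 | p2 <= t) = p1 / F(p1 | p2 <= t),

where F is the empirical CDF of primary p-values within the stratum of
SNPs at least as significant as t in the conditional trait, and the null
proportion pi0 is set to 1 (a conservative upper bound). Values are
tabulated on a regular grid over (-log10 p1, -log10 p2), optionally
averaged over random LD-pruning iterations so that strata are not
dominated by large LD blocks, monotonically regularized, and assigned to
SNPs by bilinear interpolation. The conjunctional FDR is the element-wise
maximum of the two reciprocal conditional FDRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import maximum_filter1d

from .simulate import LdPanel
from .sumstats import SumStats

_TINY = np.finfo(float).tiny


@dataclass
class FdrGrid:
    """Binned condFDR lookup over (-log10 p_primary, -log10 p_conditional).

    ``values[i, j]`` is the condFDR at primary node ``nodes[i]`` and
    conditional node ``nodes[j]``; values lie in (0, 1] and are
    non-increasing along both axes after regularization.
    """

    nodes: np.ndarray
    values: np.ndarray
    min_stratum: int = 100
    prune_iters: int = 0
    r2_prune: float = 0.1
    seed: int = 0

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.nodes, self.nodes), self.values, method="linear"
        )


def empirical_condfdr(p_query, stratum_p) -> np.ndarray:
    """Conservative condFDR of query p-values against a stratum.

    F is the inclusive empirical CDF (#{p <= q} / n) of the stratum's
    primary p-values; the estimate is min(1, q / F(q)), and 1 where the
    stratum contains no p-value at or below q.
    """
    sp = np.sort(np.asarray(stratum_p, dtype=float))
    q = np.atleast_1d(np.asarray(p_query, dtype=float))
    cnt = np.searchsorted(sp, q, side="right")
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(cnt > 0, np.minimum(1.0, q * sp.size / np.maximum(cnt, 1)), 1.0)
    return val


def _grid_once(
    p1: np.ndarray, p2: np.ndarray, nodes: np.ndarray, min_stratum: int
) -> np.ndarray:
    """One pass of the 2D lookup: columns are conditional strata.

    Strata smaller than ``min_stratum`` inherit the parent (next looser)
    stratum's column.
    """
    order = np.argsort(p2, kind="stable")
    p2_sorted = p2[order]
    p1_by_p2 = p1[order]
    p_nodes = np.power(10.0, -nodes)
    nx = nodes.size
    values = np.ones((nx, nx))
    prev = np.minimum(1.0, p_nodes)  # ultimate fallback: condFDR = p1
    for j, y in enumerate(nodes):
        t = 10.0 ** (-y)
        size = int(np.searchsorted(p2_sorted, t, side="right"))
        if size >= min_stratum:
            prev = empirical_condfdr(p_nodes, p1_by_p2[:size])
        values[:, j] = prev
    return values


def _prune_masks(
    panel: LdPanel,
    snp_ids,
    r2_prune: float,
    iterations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random LD-pruning masks: one SNP kept per local r2 > r2_prune clump.

    Each iteration draws iid priorities and keeps SNPs that maximize the
    priority within their correlated neighbourhood (index lag at which the
    panel's AR(1) r2 still exceeds ``r2_prune``), a vectorized random
    thinning that keeps approximately independent representatives.
    """
    idx = panel.indices(snp_ids)
    max_lag = panel.max_lag(r2_prune)
    n_panel = len(panel)
    masks = np.empty((iterations, idx.size), dtype=bool)
    if max_lag == 0:
        masks[:] = True
        return masks
    block_sizes = np.bincount(panel.block_id)
    if len(set(block_sizes)) != 1:
        raise ValueError("random pruning requires uniform panel blocks")
    bs = int(block_sizes[0])
    window = 2 * max_lag + 1
    for it in range(iterations):
        prio = np.full(n_panel, -np.inf)
        prio[idx] = rng.random(idx.size)
        local_max = maximum_filter1d(
            prio.reshape(-1, bs), size=window, axis=1, mode="constant", cval=-np.inf
        ).reshape(-1)
        masks[it] = prio[idx] >= local_max[idx]
    return masks


def _select_levels(values: np.ndarray, max_levels: int = 400) -> np.ndarray:
    """Distinct grid levels, thinned to a manageable monotone set."""
    levels = np.unique(values)
    if levels.size > max_levels:
        q = np.linspace(0.0, 1.0, max_levels)
        levels = np.unique(np.quantile(levels, q))
    return levels


def _union_region_correction(
    values: np.ndarray,
    nodes: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    masks: np.ndarray | None = None,
) -> np.ndarray:
    """Re-map grid values so thresholding controls clump-level FDR.

    Judging every SNP at its own conditional stratum rejects the union of
    per-stratum regions; each region is individually calibrated, so the
    union collects more nulls than any single one and the raw statistic is
    anti-conservative. For each level v this computes a BH-style estimate
    of the union region's FDR and assigns max(v, estimate), a monotone
    re-mapping that preserves SNP ranking.

    Numerator: expected null leakage with pi0 = 1 — for every conditional
    bin, its total SNP count times the largest primary p-value admitted at
    level v (counting every SNP gives an LD clump as many chances to cross
    the boundary as it has members, an upper bound on the expected number
    of false clumps). Denominator: discoveries counted on random-pruned
    subsets (``masks``; one SNP per r2 clump) — approximately independent
    signals, the granularity at which genomic risk loci are declared; a
    clump counts only insofar as its random representative is discovered,
    which further discounts weak clusters. See the methods note for the
    derivation.
    """
    nx = nodes.size
    step = nodes[1] - nodes[0]
    # per-SNP raw values via the same bilinear lookup used downstream
    interp = RegularGridInterpolator((nodes, nodes), values, method="linear")
    x = np.clip(-np.log10(p1), nodes[0], nodes[-1])
    y = np.clip(-np.log10(p2), nodes[0], nodes[-1])
    raw_snp = interp(np.column_stack([x, y]))

    levels = _select_levels(values)
    ybin = np.clip((y / step).astype(int), 0, nx - 1)
    n_bin = np.bincount(ybin, minlength=nx).astype(float)
    if masks is None:
        masks = np.ones((1, p1.size), dtype=bool)
    n_disc = np.zeros(levels.size)
    for mask in masks:
        n_disc += np.searchsorted(np.sort(raw_snp[mask]), levels, side="right")
    n_disc /= masks.shape[0]

    # per column j: largest admissible p1 at each level; the boundary is
    # loosened by one node because bilinear interpolation between nodes
    # admits SNPs slightly beyond the node-level region
    leak = np.zeros(levels.size)
    p_nodes = np.power(10.0, -nodes)
    for j in range(nx):
        col_rev = values[::-1, j]  # non-decreasing (values fall along x)
        cnt = np.searchsorted(col_rev, levels, side="right")
        x0 = np.maximum(nx - cnt - 1, 0)
        contrib = np.where(cnt > 0, p_nodes[x0], 0.0)
        leak += n_bin[j] * contrib
    with np.errstate(divide="ignore", invalid="ignore"):
        union_fdr = np.minimum(1.0, leak / np.maximum(n_disc, 1e-12))
    union_fdr = np.maximum.accumulate(union_fdr)  # monotone in the level
    corrected = np.maximum(levels, union_fdr)
    return np.interp(values, levels, corrected)


def build_condfdr_grid(
    primary: SumStats,
    conditional: SumStats,
    grid_step: float = 0.1,
    grid_max: float = 20.0,
    min_stratum: int = 100,
    panel: LdPanel | None = None,
    prune_iters: int = 20,
    r2_prune: float = 0.1,
    curve_correction: bool = True,
    seed: int = 0,
) -> FdrGrid:
    """Tabulate condFDR(primary | conditional) on a regular log grid.

    With a ``panel``, the grid is averaged over ``prune_iters`` random
    LD-pruning iterations (one SNP kept per r2 > ``r2_prune`` clump) so
    stratum CDFs are not distorted by LD-induced dependence. Monotone
    regularization (cumulative minimum along the primary axis, then along
    the conditional axis) is applied next, followed by the union-region
    FDR correction (``curve_correction``; see
    :func:`_union_region_correction`) which keeps thresholding the
    per-SNP values conservative.
    """
    if len(primary) != len(conditional) or not primary.snp.equals(conditional.snp):
        raise ValueError("inputs must be harmonized to the same SNP order")
    nodes = np.round(np.arange(0.0, grid_max + grid_step / 2, grid_step), 10)
    p1, p2 = primary.p, conditional.p

    if panel is not None and prune_iters > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
        masks = _prune_masks(panel, primary.snp, r2_prune, prune_iters, rng)
        acc = np.zeros((nodes.size, nodes.size))
        for mask in masks:
            acc += _grid_once(p1[mask], p2[mask], nodes, min_stratum)
        values = acc / masks.shape[0]
        iters = prune_iters
    else:
        masks = None
        values = _grid_once(p1, p2, nodes, min_stratum)
        iters = 0

    # enforce monotone non-increase in significance along both axes
    values = np.minimum.accumulate(values, axis=0)
    values = np.minimum.accumulate(values, axis=1)
    values = np.clip(values, _TINY, 1.0)
    if curve_correction:
        values = _union_region_correction(values, nodes, p1, p2, masks)
        values = np.minimum.accumulate(values, axis=0)
        values = np.minimum.accumulate(values, axis=1)
        values = np.clip(values, _TINY, 1.0)
    return FdrGrid(
        nodes=nodes,
        values=values,
        min_stratum=min_stratum,
        prune_iters=iters,
        r2_prune=r2_prune,
        seed=seed,
    )


def assign_condfdr(
    grid: FdrGrid, primary: SumStats, conditional: SumStats
) -> np.ndarray:
    """Per-SNP condFDR by bilinear interpolation of the grid.

    Coordinates beyond the grid range are clamped to the boundary cell;
    results are clipped to (0, 1].
    """
    if len(primary) != len(conditional) or not primary.snp.equals(conditional.snp):
        raise ValueError("inputs must be harmonized to the same SNP order")
    x = np.clip(-np.log10(primary.p), grid.nodes[0], grid.nodes[-1])
    y = np.clip(-np.log10(conditional.p), grid.nodes[0], grid.nodes[-1])
    vals = grid.interpolator()(np.column_stack([x, y]))
    return np.clip(vals, _TINY, 1.0)


def conjunctional_fdr(cond_ab, cond_ba) -> np.ndarray:
    """conjFDR: element-wise maximum of the two reciprocal condFDRs."""
    a = np.asarray(cond_ab, dtype=float)
    b = np.asarray(cond_ba, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return np.maximum(a, b)


def conjunctional_fdr_corrected(
    grid_ab: FdrGrid,
    grid_ba: FdrGrid,
    primary: SumStats,
    conditional: SumStats,
    panel: LdPanel | None = None,
    prune_iters: int = 20,
    r2_prune: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """conjFDR with an FDR calibration of the joint discovery region.

    The raw conjFDR (element-wise max of the two condFDRs) asks both
    directions to be individually credible, but its discovery set is the
    small intersection {condFDR_AB <= v and condFDR_BA <= v}, into which a
    SNP causal for only one trait passes easily: its true-signal direction
    is trivially small and its null direction needs only a modest chance
    p-value amplified by stratum enrichment. This re-maps the raw conjFDR
    levels by a BH-style estimate of the joint region's "null for either
    trait" FDR: expected uniform-null leakage of each trait across the
    joint region boundary, summed, over the discovery count on
    random-pruned subsets (one SNP per LD clump, as in
    :func:`_union_region_correction`). The mapping is monotone, so SNP
    ranking is unchanged.
    """
    nodes = grid_ab.nodes
    if grid_ba.nodes.shape != nodes.shape or not np.allclose(grid_ba.nodes, nodes):
        raise ValueError("grids must share the same node lattice")
    nx = nodes.size
    step = nodes[1] - nodes[0]
    p1, p2 = primary.p, conditional.p
    raw = np.maximum(
        assign_condfdr(grid_ab, primary, conditional),
        assign_condfdr(grid_ba, conditional, primary),
    )
    # joint surface on the lattice: W[i, j] at (-log10 p1 = nodes[i],
    # -log10 p2 = nodes[j]); non-increasing along both axes
    W = np.maximum(grid_ab.values, grid_ba.values.T)

    x = np.clip(-np.log10(p1), nodes[0], nodes[-1])
    y = np.clip(-np.log10(p2), nodes[0], nodes[-1])
    xbin = np.clip((x / step).astype(int), 0, nx - 1)
    ybin = np.clip((y / step).astype(int), 0, nx - 1)

    if panel is not None and prune_iters > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
        masks = _prune_masks(panel, primary.snp, r2_prune, prune_iters, rng)
    else:
        masks = np.ones((1, p1.size), dtype=bool)

    levels = _select_levels(W)
    n_bin1 = np.bincount(xbin, minlength=nx).astype(float)
    n_bin2 = np.bincount(ybin, minlength=nx).astype(float)
    n_disc = np.zeros(levels.size)
    for mask in masks:
        n_disc += np.searchsorted(np.sort(raw[mask]), levels, side="right")
    n_disc /= masks.shape[0]

    p_nodes = np.power(10.0, -nodes)
    leak = np.zeros(levels.size)
    for j in range(nx):
        # trait-1 nulls in conditional bin j: largest admissible p1
        cnt = np.searchsorted(W[::-1, j], levels, side="right")
        x0 = np.maximum(nx - cnt - 1, 0)
        leak += n_bin2[j] * np.where(cnt > 0, p_nodes[x0], 0.0)
        # trait-2 nulls in primary bin j: largest admissible p2
        cnt = np.searchsorted(W[j, ::-1], levels, side="right")
        y0 = np.maximum(nx - cnt - 1, 0)
        leak += n_bin1[j] * np.where(cnt > 0, p_nodes[y0], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        joint_fdr = np.minimum(1.0, leak / np.maximum(n_disc, 1e-12))
    joint_fdr = np.maximum.accumulate(joint_fdr)
    corrected = np.maximum(levels, joint_fdr)
    return np.clip(np.interp(raw, levels, corrected), _TINY, 1.0)


def unconditional_fdr(p) -> np.ndarray:
    """Conservative per-SNP empirical FDR without conditioning.

    Equals p / F(p) with F the inclusive ECDF of all p-values (the t = 1
    column of the grid), monotonized from the largest p downwards — the
    pi0 = 1 Benjamini-Hochberg-style q-value.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    sp = p[order]
    F = np.searchsorted(sp, sp, side="right") / n
    q = np.minimum(1.0, sp / F)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(n)
    out[order] = q
    return out
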
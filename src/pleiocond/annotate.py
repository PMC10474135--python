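"""Positional gene mapping and gene-set over-representation.

Database-free analogue of the functional-annotation stage: candidate SNPs
are mapped to genes by physical position within a window (default 10 kb),
gene sets are tested for over-representation with an upper-tail
hypergeometric test, and p-values are Bonferroni-corrected. Precomputed
SNP-to-gene tables from other mapping strategies (eQTL, chromatin
interaction) can be supplied to combine evidence across strategies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumStats


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's coordinates (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    symbol: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_genes(path) -> list[GeneAnnotation]:
    """Read a gene table (TSV with gene_id, chrom, start, end[, symbol])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneAnnotation(
            str(r.gene_id), str(r.chrom), int(r.start), int(r.end),
            str(getattr(r, "symbol", "")),
        )
        for r in df.itertuples(index=False)
    ]


def read_gmt(path) -> dict[str, set]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def map_genes_positional(
    candidate_snps: SumStats,
    genes: list[GeneAnnotation],
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Map SNPs to all genes within ``window_bp`` of the gene body.

    A pair (snp, gene) is emitted iff gene.start - window <= pos <=
    gene.end + window on the same chromosome; one SNP may map to several
    genes. Returns a long table with snp, gene_id, symbol and distance (0
    inside the gene body).
    """
    df = candidate_snps.df
    rows = []
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for snp, chrom, pos in zip(df["snp"], df["chrom"], df["pos"]):
        for g in by_chrom.get(chrom, ()):
            if g.start - window_bp <= pos <= g.end + window_bp:
                dist = max(g.start - pos, pos - g.end, 0)
                rows.append(
                    {"snp": snp, "gene_id": g.gene_id, "symbol": g.symbol,
                     "distance": int(dist)}
                )
    return pd.DataFrame(rows, columns=["snp", "gene_id", "symbol", "distance"])


def combine_mapping_strategies(
    tables: list[pd.DataFrame], min_strategies: int = 2
) -> set:
    """Genes supported by at least ``min_strategies`` SNP-to-gene tables.

    Each table needs a ``gene_id`` column (e.g. the positional mapping plus
    externally computed eQTL / chromatin-interaction mappings).
    """
    counts: dict[str, int] = {}
    for t in tables:
        for g in set(t["gene_id"]):
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_strategies}


def hypergeometric_enrichment(
    mapped_genes: set, gene_set: set, universe: set
) -> tuple[float, int]:
    """Upper-tail hypergeometric over-representation test.

    Returns P(X >= overlap) with population |universe|, |gene_set|
    successes, |mapped_genes| draws, plus the observed overlap count.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not gene_set <= universe or not mapped_genes <= universe:
        raise ValueError("gene_set and mapped_genes must be subsets of universe")
    M, K, N = len(universe), len(gene_set), len(mapped_genes)
    k = len(mapped_genes & gene_set)
    p = float(stats.hypergeom.sf(k - 1, M, K, N))  # P(X >= k)
    return min(p, 1.0), k


def bonferroni_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction: adjusted = min(1, m*p); significant iff < alpha."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    adj = np.minimum(1.0, p.size * p)
    return adj, adj < alpha


def gene_set_table(
    mapped_genes: set,
    gene_sets: dict[str, set],
    universe: set,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of every gene set, Bonferroni-corrected."""
    names = sorted(gene_sets)
    results = [
        hypergeometric_enrichment(mapped_genes, gene_sets[n] & universe, universe)
        for n in names
    ]
    p = np.array([r[0] for r in results]) if results else np.array([])
    adj, sig = bonferroni_adjust(p, alpha) if len(p) else (p, p.astype(bool))
    return pd.DataFrame(
        {
            "gene_set": names,
            "overlap": [r[1] for r in results],
            "set_size": [len(gene_sets[n] & universe) for n in names],
            "p": p,
            "p_bonferroni": adj,
            "significant": sig,
        }
    )
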
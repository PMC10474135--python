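"""Reading, validation, harmonization and filtering of GWAS summary statistics.

A :class:`SumStats` holds one trait's per-SNP association records (id,
coordinates, alleles, signed z-score, two-sided p-value, effective sample
size). Coordinates are 1-based inclusive throughout; BED export elsewhere
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical internal column order
COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "z", "p", "n"]

#: default external column names (tab-separated files)
DEFAULT_COLUMN_MAP = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "z": "Z",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
}


class SumStatsError(ValueError):
    """Raised on malformed or inconsistent summary statistics."""


@dataclass(frozen=True)
class ExclusionRegion:
    """A closed genomic interval [start, end] (1-based, inclusive) to drop."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"exclusion region {self.label!r}: start > end")


#: regions with complex long-range LD excluded from all FDR analyses:
#: the extended MHC and the 8p23.1 inversion (hg19 coordinates).
DEFAULT_EXCLUSION_REGIONS = (
    ExclusionRegion("6", 25119106, 33854733, "MHC"),
    ExclusionRegion("8", 7242715, 12483982, "8p23.1"),
)


@dataclass
class SumStats:
    """Validated per-SNP summary statistics for a single trait.

    The backing frame has columns ``snp, chrom, pos, a1, a2, z, p, n``.
    ``a1`` is the effect allele; ``z`` is signed with respect to ``a1``.
    p and z are mutually consistent: p = 2*Phi(-|z|).
    """

    df: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SumStatsError(f"missing columns: {missing}")
        df = df[COLUMNS].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        if df["snp"].duplicated().any():
            dups = df.loc[df["snp"].duplicated(), "snp"].head().tolist()
            raise SumStatsError(f"duplicate snp ids, e.g. {dups}")
        if (df["pos"] < 1).any():
            raise SumStatsError("positions must be >= 1")
        if (df["a1"] == df["a2"]).any():
            raise SumStatsError("effect allele equals other allele for some SNPs")
        p = df["p"].to_numpy(float)
        z = df["z"].to_numpy(float)
        if ((p <= 0) | (p > 1)).any():
            raise SumStatsError("p-values must lie in (0, 1]")
        p_from_z = 2.0 * stats.norm.sf(np.abs(z))
        bad = ~np.isclose(p_from_z, p, rtol=1e-6, atol=1e-300)
        if bad.any():
            raise SumStatsError(
                f"{bad.sum()} SNPs have inconsistent p and z "
                f"(first: {df.loc[np.flatnonzero(bad)[0], 'snp']})"
            )
        if (df["n"].to_numpy(float) <= 0).any():
            raise SumStatsError("sample sizes must be positive")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp(self) -> pd.Series:
        return self.df["snp"]

    @property
    def p(self) -> np.ndarray:
        return self.df["p"].to_numpy(float)

    @property
    def z(self) -> np.ndarray:
        return self.df["z"].to_numpy(float)

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy(np.int64)

    @property
    def chrom(self) -> pd.Series:
        return self.df["chrom"]

    def write(self, path, column_map: dict | None = None) -> None:
        """Write as a tab-separated file with external column names."""
        cmap = dict(DEFAULT_COLUMN_MAP)
        if column_map:
            cmap.update(column_map)
        out = self.df.rename(
            columns={k: cmap[k] for k in COLUMNS if k in cmap}
        )
        out.to_csv(path, sep="\t", index=False)


def _zscore_from_p(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Reconstruct signed z from a two-sided p-value and an effect sign."""
    return np.sign(sign) * stats.norm.isf(p / 2.0)


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait: str = "trait",
    default_n: float | None = None,
) -> SumStats:
    """Read a tab-separated summary-statistics file into a :class:`SumStats`.

    The file must carry at minimum SNP id, chromosome, position, both
    alleles, and either a z-score or a p-value plus a signed effect (beta).
    If z is absent it is reconstructed as sign(beta) * Phi^-1(1 - p/2).
    Rows with p outside (0, 1], missing or non-ACGT alleles are dropped and
    counted in the log. ``default_n`` fills a missing N column.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype={cmap["chrom"]: str})
    if raw.empty:
        raise SumStatsError(f"{path}: empty summary-statistics file")

    for key in ("snp", "chrom", "pos", "a1", "a2"):
        if cmap[key] not in raw.columns:
            raise SumStatsError(f"{path}: missing mandatory column {cmap[key]!r}")
    has_z = cmap["z"] in raw.columns
    has_p = cmap["p"] in raw.columns
    has_beta = cmap["beta"] in raw.columns
    if not has_z and not (has_p and has_beta):
        raise SumStatsError(
            f"{path}: need either column {cmap['z']!r} or "
            f"both {cmap['p']!r} and {cmap['beta']!r}"
        )

    df = pd.DataFrame(
        {
            "snp": raw[cmap["snp"]].astype(str),
            "chrom": raw[cmap["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[cmap["pos"]], errors="coerce"),
            "a1": raw[cmap["a1"]].astype(str).str.upper(),
            "a2": raw[cmap["a2"]].astype(str).str.upper(),
        }
    )
    n_in = len(df)

    keep = (
        df["pos"].notna()
        & df["a1"].isin(VALID_ALLELES)
        & df["a2"].isin(VALID_ALLELES)
        & (df["a1"] != df["a2"])
    )

    if has_z:
        z = pd.to_numeric(raw[cmap["z"]], errors="coerce").to_numpy(float)
        keep &= np.isfinite(z)
        p = 2.0 * stats.norm.sf(np.abs(z))
        # guard against numerical underflow to exactly zero
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    else:
        p = pd.to_numeric(raw[cmap["p"]], errors="coerce").to_numpy(float)
        beta = pd.to_numeric(raw[cmap["beta"]], errors="coerce").to_numpy(float)
        keep &= np.isfinite(p) & (p > 0) & (p <= 1) & np.isfinite(beta)
        with np.errstate(invalid="ignore"):
            z = _zscore_from_p(p, beta)
        z = np.where(np.isfinite(z), z, 0.0)

    if cmap["n"] in raw.columns:
        n = pd.to_numeric(raw[cmap["n"]], errors="coerce").to_numpy(float)
    elif default_n is not None:
        n = np.full(n_in, float(default_n))
    else:
        raise SumStatsError(
            f"{path}: missing mandatory column {cmap['n']!r} (or pass default_n)"
        )
    keep &= np.isfinite(n) & (n > 0)

    dropped = int(n_in - keep.sum())
    if dropped:
        logger.info("%s: dropped %d/%d invalid rows", path, dropped, n_in)
    if not keep.any():
        raise SumStatsError(f"{path}: no valid rows after filtering")

    df = df[keep.to_numpy()].reset_index(drop=True)
    out = df.assign(z=z[keep.to_numpy()], p=p[keep.to_numpy()], n=n[keep.to_numpy()])
    out = out.drop_duplicates("snp", keep="first")
    return SumStats(out[COLUMNS], trait=trait)


def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    """Strand-ambiguous (palindromic) SNPs: A/T or C/G pairs."""
    return a2 == a1.map(_COMPLEMENT)


def harmonize_pair(a: SumStats, b: SumStats) -> tuple[SumStats, SumStats]:
    """Align two traits to the same SNPs, effect alleles and row order.

    SNPs are intersected on id; alleles are matched allowing an allele swap
    (which flips the sign of b's z) and a strand complement. Strand-ambiguous
    (A/T, C/G) SNPs are removed because their orientation cannot be resolved
    without allele frequencies. Raises if fewer than 1% of SNPs are shared
    (likely a genome-build mismatch).
    """
    da, db = a.df, b.df
    merged = da.merge(db, on="snp", suffixes=("_a", "_b"), how="inner")
    if len(merged) < 0.01 * min(len(da), len(db)):
        raise SumStatsError(
            f"only {len(merged)} SNPs shared between traits; "
            "possible genome-build or id-scheme mismatch"
        )

    amb = _is_ambiguous(merged["a1_a"], merged["a2_a"]) | _is_ambiguous(
        merged["a1_b"], merged["a2_b"]
    )
    m = merged[~amb].copy()

    ca1 = m["a1_b"].map(_COMPLEMENT)
    ca2 = m["a2_b"].map(_COMPLEMENT)
    same = (m["a1_a"] == m["a1_b"]) & (m["a2_a"] == m["a2_b"])
    swap = (m["a1_a"] == m["a2_b"]) & (m["a2_a"] == m["a1_b"])
    comp = (m["a1_a"] == ca1) & (m["a2_a"] == ca2)
    comp_swap = (m["a1_a"] == ca2) & (m["a2_a"] == ca1)

    matched = same | swap | comp | comp_swap
    m = m[matched].copy()
    flip = (swap | comp_swap)[matched]
    m.loc[flip, "z_b"] = -m.loc[flip, "z_b"]

    n_removed = len(merged) - len(m)
    if n_removed:
        logger.info(
            "harmonize: removed %d SNPs (%d ambiguous, %d allele-mismatched)",
            n_removed,
            int(amb.sum()),
            int((~matched).sum()),
        )

    def _side(suffix: str, trait: str) -> SumStats:
        cols = {
            "snp": m["snp"],
            "chrom": m[f"chrom_{suffix}"],
            "pos": m[f"pos_{suffix}"],
            # both traits are reported on trait a's allele orientation
            "a1": m["a1_a"],
            "a2": m["a2_a"],
            "z": m[f"z_{suffix}"],
            "p": 2.0 * stats.norm.sf(np.abs(m[f"z_{suffix}"].to_numpy(float))),
            "n": m[f"n_{suffix}"],
        }
        return SumStats(pd.DataFrame(cols), trait=trait)

    return _side("a", a.trait), _side("b", b.trait)


def apply_exclusions(
    s: SumStats, regions: tuple[ExclusionRegion, ...] = DEFAULT_EXCLUSION_REGIONS
) -> SumStats:
    """Drop all SNPs falling inside any exclusion region (closed intervals)."""
    keep = np.ones(len(s), dtype=bool)
    chrom = s.chrom.to_numpy()
    pos = s.pos
    for r in regions:
        keep &= ~((chrom == r.chrom) & (pos >= r.start) & (pos <= r.end))
    removed = int((~keep).sum())
    if removed:
        logger.info("exclusions: removed %d SNPs (%s)", removed, s.trait)
    return SumStats(s.df[keep], trait=s.trait)


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Effective sample size of a case-control GWAS: 4/(1/n_cases + 1/n_controls).

    This is the size of the balanced design with the same power; for a
    balanced study it equals the total sample size.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)
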
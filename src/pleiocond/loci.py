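"""Genomic risk-locus definition from per-SNP FDR values and LD.

Implements the FUMA-style clumping hierarchy:

* independent significant SNPs — FDR < 0.05, mutually r2 < 0.6, selected
  greedily in ascending FDR order;
* lead SNPs — the subset of independent significant SNPs in approximate
  linkage equilibrium (mutual r2 < 0.1);
* candidate SNPs — FDR < 0.1 and r2 >= 0.6 with at least one independent
  significant SNP;
* loci — intervals spanned by each lead SNP's candidate set, with leads
  whose intervals lie within 250 kb merged into a single locus.

Plus interval intersection across analyses, unique-locus merging, and
lead-SNP effect-direction concordance between two harmonized traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import LdPanel
from .sumstats import SumStats


@dataclass
class LocusThresholds:
    """Clumping thresholds. ``merge_on`` selects whether the 250 kb merge
    rule measures the gap between locus intervals ("interval") or between
    lead-SNP positions ("lead")."""

    sig: float = 0.05
    cand: float = 0.1
    r2_indep: float = 0.6
    r2_lead: float = 0.1
    merge_kb: float = 250.0
    window_bp: int = 1_000_000
    merge_on: str = "interval"


@dataclass
class Locus:
    """A genomic risk locus (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    lead_snps: list
    independent_significant_snps: list
    candidate_snps: list
    min_fdr: float
    analysis_label: str = ""

    @property
    def lead(self) -> str:
        """Primary lead SNP (smallest FDR among leads)."""
        return self.lead_snps[0]

    def overlaps(self, other: "Locus") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def pairwise_r2(panel: LdPanel, snps) -> pd.DataFrame:
    """Symmetric r2 table (squared dosage correlation) for the given SNPs."""
    snps = list(snps)
    r2 = panel.r2_matrix(snps)
    return pd.DataFrame(r2, index=snps, columns=snps)


def _windowed_r2(panel, df: pd.DataFrame, window_bp: int) -> np.ndarray:
    """r2 among the universe SNPs, zeroed across chromosomes / the window."""
    r2 = panel.r2_matrix(df["snp"].to_numpy())
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    near = (np.abs(pos[:, None] - pos[None, :]) <= window_bp) & (
        chrom[:, None] == chrom[None, :]
    )
    out = np.where(near, r2, 0.0)
    np.fill_diagonal(out, 1.0)
    return out


def define_loci(
    scores,
    sumstats: SumStats,
    panel: LdPanel,
    thresholds: LocusThresholds | None = None,
    analysis_label: str = "",
    tiebreak=None,
) -> list[Locus]:
    """Clump per-SNP FDR values into genomic risk loci.

    ``scores`` is aligned with ``sumstats``. Selection is greedy in
    ascending (FDR, tiebreak, position, id) order so the result is
    invariant to the input row order; ``tiebreak`` defaults to the
    trait's p-value, which separates the frequent exact ties produced by
    the monotone/plateau structure of the FDR surface (for conjunctional
    scores pass e.g. the element-wise max of the two p-values). Every
    candidate SNP is attached to exactly one independent significant SNP
    (its strongest-r2 partner, earlier greedy order breaking ties) so loci
    partition the candidate set. Returns an empty list when nothing passes
    the significance threshold.
    """
    th = thresholds or LocusThresholds()
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(sumstats):
        raise ValueError("scores and sumstats are not aligned")
    if tiebreak is None:
        tiebreak = sumstats.p
    tiebreak = np.asarray(tiebreak, dtype=float)
    if tiebreak.shape[0] != len(sumstats):
        raise ValueError("tiebreak and sumstats are not aligned")

    keep = scores < th.cand
    uni = sumstats.df.loc[keep, ["snp", "chrom", "pos"]].reset_index(drop=True)
    uni["fdr"] = scores[keep]
    uni["tie"] = tiebreak[keep]
    if not (uni["fdr"] < th.sig).any():
        return []

    # deterministic greedy order: ascending FDR, then signal strength,
    # then position, then id
    order = np.lexsort(
        (
            uni["snp"].to_numpy(),
            uni["pos"].to_numpy(),
            uni["tie"].to_numpy(),
            uni["fdr"].to_numpy(),
        )
    )
    r2 = _windowed_r2(panel, uni, th.window_bp)
    fdr = uni["fdr"].to_numpy()

    indep: list[int] = []
    for i in order:
        if fdr[i] >= th.sig:
            continue
        if all(r2[i, j] < th.r2_indep for j in indep):
            indep.append(i)

    leads: list[int] = []
    lead_of: dict[int, int] = {}
    for i in indep:  # already in greedy order
        partner = next((l for l in leads if r2[i, l] >= th.r2_lead), None)
        if partner is None:
            leads.append(i)
            lead_of[i] = i
        else:
            lead_of[i] = partner

    # attach each candidate-universe SNP to its strongest-r2 independent
    # significant SNP (if r2 >= r2_indep); earlier greedy order breaks ties
    indep_arr = np.array(indep)
    sub = r2[:, indep_arr]
    best = np.argmax(sub, axis=1)
    best_r2 = sub[np.arange(len(uni)), best]
    owner = np.where(best_r2 >= th.r2_indep, indep_arr[best], -1)
    owner[indep_arr] = indep_arr  # independent SNPs own themselves

    members: dict[int, list[int]] = {l: [] for l in leads}
    for snp_i, own in enumerate(owner):
        if own >= 0:
            members[lead_of[own]].append(snp_i)

    pos = uni["pos"].to_numpy()
    chrom = uni["chrom"].to_numpy()
    snp = uni["snp"].to_numpy()
    loci = []
    for l in leads:
        mem = members[l]
        sig_members = [i for i in indep if lead_of[i] == l]
        loci.append(
            Locus(
                chrom=str(chrom[l]),
                start=int(pos[mem].min()),
                end=int(pos[mem].max()),
                lead_snps=[snp[l]],
                independent_significant_snps=sorted(
                    (snp[i] for i in sig_members), key=lambda s: fdr[snp == s][0]
                ),
                candidate_snps=sorted(snp[mem]),
                min_fdr=float(fdr[mem].min()),
                analysis_label=analysis_label,
            )
        )
    return _merge_nearby(
        loci,
        th,
        {s: float(f) for s, f in zip(snp, fdr)},
        {s: int(p) for s, p in zip(snp, pos)},
    )


def _merge_nearby(
    loci: list[Locus], th: LocusThresholds, fdr_of: dict, pos_of: dict
) -> list[Locus]:
    """Merge loci whose gap is within the 250 kb LD-block rule."""
    loci = sorted(loci, key=lambda l: (l.chrom, l.start, l.end))
    merge_bp = th.merge_kb * 1000.0
    out: list[Locus] = []
    for loc in loci:
        if out and out[-1].chrom == loc.chrom:
            prev = out[-1]
            if th.merge_on == "lead":
                gap = min(
                    abs(pos_of[s] - pos_of[t])
                    for s in prev.lead_snps
                    for t in loc.lead_snps
                )
            else:
                gap = max(loc.start - prev.end, 0)
            if gap <= merge_bp:
                leads = sorted(
                    prev.lead_snps + loc.lead_snps, key=lambda s: fdr_of[s]
                )
                out[-1] = replace(
                    prev,
                    start=min(prev.start, loc.start),
                    end=max(prev.end, loc.end),
                    lead_snps=leads,
                    independent_significant_snps=sorted(
                        set(prev.independent_significant_snps)
                        | set(loc.independent_significant_snps),
                        key=lambda s: fdr_of[s],
                    ),
                    candidate_snps=sorted(
                        set(prev.candidate_snps) | set(loc.candidate_snps)
                    ),
                    min_fdr=min(prev.min_fdr, loc.min_fdr),
                )
                continue
        out.append(loc)
    return out


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    """Tabular view (one row per locus)."""
    return pd.DataFrame(
        {
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "lead_snp": [l.lead for l in loci],
            "n_lead": [len(l.lead_snps) for l in loci],
            "n_indep_sig": [len(l.independent_significant_snps) for l in loci],
            "n_candidates": [len(l.candidate_snps) for l in loci],
            "min_fdr": [l.min_fdr for l in loci],
            "analysis": [l.analysis_label for l in loci],
        }
    )


def loci_to_bed(loci: list[Locus], path) -> None:
    """Write loci as BED (0-based half-open) with lead SNP and min FDR."""
    with open(path, "w") as fh:
        for l in sorted(loci, key=lambda l: (l.chrom, l.start)):
            fh.write(
                f"{l.chrom}\t{l.start - 1}\t{l.end}\t{l.lead}\t"
                f"{l.min_fdr:.6g}\t{len(l.candidate_snps)}\n"
            )


@dataclass
class OverlapResult:
    """Pairing of physically overlapping loci between two analyses."""

    pairs: list  # (index in a, index in b)
    only_a: list
    only_b: list

    @property
    def n_shared(self) -> int:
        return len(self.pairs)


def overlap_loci(a: list[Locus], b: list[Locus]) -> OverlapResult:
    """Pair loci from two analyses that share at least one base pair."""
    pairs = [
        (i, j)
        for i, la in enumerate(a)
        for j, lb in enumerate(b)
        if la.overlaps(lb)
    ]
    in_a = {i for i, _ in pairs}
    in_b = {j for _, j in pairs}
    return OverlapResult(
        pairs=pairs,
        only_a=[i for i in range(len(a)) if i not in in_a],
        only_b=[j for j in range(len(b)) if j not in in_b],
    )


def merge_unique_loci(analyses: list[list[Locus]]) -> list[Locus]:
    """Unique loci across analyses: iterative merge of overlapping intervals.

    Physically overlapping loci from any analyses collapse into one; the
    result's labels concatenate the contributing analyses.
    """
    flat = sorted(
        (l for lst in analyses for l in lst), key=lambda l: (l.chrom, l.start, l.end)
    )
    out: list[Locus] = []
    for loc in flat:
        if out and out[-1].overlaps(loc):
            prev = out[-1]
            labels = [x for x in prev.analysis_label.split("+") if x]
            if loc.analysis_label and loc.analysis_label not in labels:
                labels.append(loc.analysis_label)
            out[-1] = replace(
                prev,
                start=min(prev.start, loc.start),
                end=max(prev.end, loc.end),
                lead_snps=prev.lead_snps
                + [s for s in loc.lead_snps if s not in prev.lead_snps],
                independent_significant_snps=sorted(
                    set(prev.independent_significant_snps)
                    | set(loc.independent_significant_snps)
                ),
                candidate_snps=sorted(
                    set(prev.candidate_snps) | set(loc.candidate_snps)
                ),
                min_fdr=min(prev.min_fdr, loc.min_fdr),
                analysis_label="+".join(labels),
            )
        else:
            out.append(loc)
    return out


def effect_concordance(
    loci: list[Locus], a: SumStats, b: SumStats
) -> tuple[pd.DataFrame, float, int]:
    """Lead-SNP effect-direction concordance between two harmonized traits.

    A locus is concordant iff sign(z_a) * sign(z_b) > 0 at its primary lead
    SNP. Loci whose lead is missing from either trait, or has z = 0, are
    flagged indeterminate and excluded from the denominator. Returns the
    per-locus table, the concordant fraction, and the integer percentage.
    """
    za = dict(zip(a.snp, a.z))
    zb = dict(zip(b.snp, b.z))
    rows = []
    for l in loci:
        lead = l.lead
        z1, z2 = za.get(lead), zb.get(lead)
        if z1 is None or z2 is None or z1 == 0 or z2 == 0:
            status = "indeterminate"
        elif np.sign(z1) == np.sign(z2):
            status = "concordant"
        else:
            status = "discordant"
        rows.append(
            {
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "lead_snp": lead,
                "z_a": z1,
                "z_b": z2,
                "status": status,
            }
        )
    table = pd.DataFrame(rows)
    det = table[table["status"] != "indeterminate"] if len(table) else table
    n = len(det)
    k = int((det["status"] == "concordant").sum()) if n else 0
    frac = k / n if n else float("nan")
    pct = int(round(100.0 * frac)) if n else 0
    return table, frac, pct
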
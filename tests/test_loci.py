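"""Genomic risk-locus definition vs a brute-force oracle, plus interval ops."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleiocond import (
    Locus,
    LocusThresholds,
    define_loci,
    effect_concordance,
    merge_unique_loci,
    overlap_loci,
    pairwise_r2,
)
from pleiocond.simulate import LdPanel

from conftest import make_sumstats


# ---------------------------------------------------------------- oracle

def oracle_define_loci(snp, chrom, pos, fdr, r2, th):
    """Plain-loop reimplementation of the clumping hierarchy."""
    n = len(snp)

    def R(i, j):
        if i == j:
            return 1.0
        if chrom[i] != chrom[j] or abs(pos[i] - pos[j]) > th.window_bp:
            return 0.0
        return r2[i][j]

    uni = [i for i in range(n) if fdr[i] < th.cand]
    if not any(fdr[i] < th.sig for i in uni):
        return []
    order = sorted(uni, key=lambda i: (fdr[i], pos[i], snp[i]))

    indep = []
    for i in order:
        if fdr[i] >= th.sig:
            continue
        if all(R(i, j) < th.r2_indep for j in indep):
            indep.append(i)

    leads, lead_of = [], {}
    for i in indep:
        partner = next((l for l in leads if R(i, l) >= th.r2_lead), None)
        if partner is None:
            leads.append(i)
            lead_of[i] = i
        else:
            lead_of[i] = partner

    members = {l: set() for l in leads}
    for i in uni:
        if i in indep:
            members[lead_of[i]].add(i)
            continue
        best, best_r = None, -1.0
        for s in indep:  # greedy order; strict > keeps the earlier on ties
            if R(i, s) > best_r:
                best_r, best = R(i, s), s
        if best is not None and best_r >= th.r2_indep:
            members[lead_of[best]].add(i)

    loci = []
    for l in leads:
        mem = members[l]
        loci.append(
            dict(
                chrom=chrom[l],
                start=min(pos[i] for i in mem),
                end=max(pos[i] for i in mem),
                leads={snp[l]},
                cands={snp[i] for i in mem},
                min_fdr=min(fdr[i] for i in mem),
            )
        )
    loci.sort(key=lambda d: (d["chrom"], d["start"], d["end"]))
    merged = []
    for loc in loci:
        if (
            merged
            and merged[-1]["chrom"] == loc["chrom"]
            and max(loc["start"] - merged[-1]["end"], 0) <= th.merge_kb * 1000
        ):
            prev = merged[-1]
            prev["start"] = min(prev["start"], loc["start"])
            prev["end"] = max(prev["end"], loc["end"])
            prev["leads"] |= loc["leads"]
            prev["cands"] |= loc["cands"]
            prev["min_fdr"] = min(prev["min_fdr"], loc["min_fdr"])
        else:
            merged.append(loc)
    return merged


def random_instance(rng, n_max=12):
    n = int(rng.integers(2, n_max + 1))
    chrom = rng.choice(["1", "2"], size=n, p=[0.8, 0.2])
    pos = np.sort(rng.integers(1, 1_500_000, size=n))
    snp = np.array([f"s{i}" for i in range(n)])
    fdr = rng.uniform(0, 0.15, size=n)
    g = rng.integers(0, 3, size=(20, n)).astype(float)
    # plant some strong LD pairs so r2 >= 0.6 actually occurs
    for _ in range(n // 3):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            g[:, j] = g[:, i] + rng.normal(0, 0.3, size=20)
    panel = LdPanel(
        snp=snp, chrom=chrom, pos=pos, block_id=np.zeros(n, dtype=int),
        genotypes=g,
    )
    df = pd.DataFrame(
        {
            "snp": snp, "chrom": chrom, "pos": pos,
            "a1": "A", "a2": "G", "z": 1.0,
            "p": 2 * stats.norm.sf(1.0), "n": 100.0,
        }
    )
    from pleiocond import SumStats

    return SumStats(df), panel, fdr


def as_tuple(locus_like):
    if isinstance(locus_like, Locus):
        return (
            locus_like.chrom,
            locus_like.start,
            locus_like.end,
            frozenset(locus_like.lead_snps),
            frozenset(locus_like.candidate_snps),
            round(locus_like.min_fdr, 12),
        )
    return (
        locus_like["chrom"],
        locus_like["start"],
        locus_like["end"],
        frozenset(locus_like["leads"]),
        frozenset(locus_like["cands"]),
        round(locus_like["min_fdr"], 12),
    )


class TestDefineLociOracle:
    def test_agrees_with_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        th = LocusThresholds()
        checked = 0
        for _ in range(500):
            s, panel, fdr = random_instance(rng)
            got = define_loci(fdr, s, panel, th)
            r2 = panel.r2_matrix(s.snp.to_numpy())
            exp = oracle_define_loci(
                s.snp.to_numpy(), s.chrom.to_numpy(), s.pos, fdr, r2, th
            )
            assert sorted(map(as_tuple, got)) == sorted(map(as_tuple, exp))
            checked += len(exp)
        assert checked > 100  # the instances actually produced loci

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(7)
        s, panel, fdr = random_instance(rng, n_max=10)
        th = LocusThresholds()
        base = define_loci(fdr, s, panel, th)
        perm = rng.permutation(len(s))
        from pleiocond import SumStats

        s2 = SumStats(s.df.iloc[perm].reset_index(drop=True))
        got = define_loci(fdr[perm], s2, panel, th)
        assert sorted(map(as_tuple, base)) == sorted(map(as_tuple, got))

    def test_every_significant_snp_in_exactly_one_locus(self):
        rng = np.random.default_rng(99)
        th = LocusThresholds()
        for _ in range(100):
            s, panel, fdr = random_instance(rng)
            loci = define_loci(fdr, s, panel, th)
            sig = set(s.snp[fdr < th.sig])
            covered = [l.candidate_snps for l in loci]
            for snp_id in sig:
                assert sum(snp_id in c for c in covered) == 1


class TestDefineLociExamples:
    def _panel_from_r2(self, snp, chrom, pos, r2):
        """Panel stub realizing an exact r2 matrix via duplicated dosages."""

        class _P:
            def r2_matrix(self, ids):
                idx = [list(snp).index(i) for i in ids]
                return r2[np.ix_(idx, idx)]

        return _P()

    def test_five_snp_worked_example(self):
        # FDR [0.01, 0.02, 0.2, 0.04, 0.5]; r2(1,2)=0.8, r2(1,4)=r2(2,4)=0.05
        snp = np.array(["s1", "s2", "s3", "s4", "s5"])
        chrom = np.array(["1"] * 5)
        pos = np.array([1_000_000, 1_050_000, 1_100_000, 2_000_000, 2_100_000])
        fdr = np.array([0.01, 0.02, 0.2, 0.04, 0.5])
        r2 = np.eye(5)
        r2[0, 1] = r2[1, 0] = 0.8
        r2[0, 3] = r2[3, 0] = 0.05
        r2[1, 3] = r2[3, 1] = 0.05
        df = pd.DataFrame(
            {"snp": snp, "chrom": chrom, "pos": pos, "a1": "A", "a2": "G",
             "z": 1.0, "p": 2 * stats.norm.sf(1.0), "n": 100.0}
        )
        from pleiocond import SumStats

        loci = define_loci(
            fdr, SumStats(df), self._panel_from_r2(snp, chrom, pos, r2),
            LocusThresholds(),
        )
        assert len(loci) == 2  # ~0.9 Mb apart, not merged
        first, second = sorted(loci, key=lambda l: l.start)
        assert first.lead_snps == ["s1"]
        assert set(first.candidate_snps) == {"s1", "s2"}  # s3 fails FDR < 0.1
        assert second.lead_snps == ["s4"]
        assert set(second.candidate_snps) == {"s4"}

    def test_two_leads_within_250kb_merge(self):
        snp = np.array(["s1", "s2"])
        chrom = np.array(["1", "1"])
        pos = np.array([1_000_000, 1_200_000])  # 200 kb apart
        fdr = np.array([0.01, 0.02])
        r2 = np.eye(2)  # in linkage equilibrium
        df = pd.DataFrame(
            {"snp": snp, "chrom": chrom, "pos": pos, "a1": "A", "a2": "G",
             "z": 1.0, "p": 2 * stats.norm.sf(1.0), "n": 100.0}
        )
        from pleiocond import SumStats

        loci = define_loci(
            fdr, SumStats(df), self._panel_from_r2(snp, chrom, pos, r2),
            LocusThresholds(),
        )
        assert len(loci) == 1
        assert loci[0].lead_snps == ["s1", "s2"]
        assert (loci[0].start, loci[0].end) == (1_000_000, 1_200_000)

    def test_singleton_locus(self):
        snp = np.array(["s1"])
        df = pd.DataFrame(
            {"snp": snp, "chrom": ["1"], "pos": [5_000_000], "a1": "A",
             "a2": "G", "z": 1.0, "p": 2 * stats.norm.sf(1.0), "n": 100.0}
        )
        from pleiocond import SumStats

        loci = define_loci(
            np.array([0.01]), SumStats(df),
            self._panel_from_r2(snp, np.array(["1"]), np.array([5_000_000]), np.eye(1)),
            LocusThresholds(),
        )
        assert len(loci) == 1
        assert loci[0].start == loci[0].end == 5_000_000

    def test_no_significant_snp_gives_empty_list(self, small_pair, small_panel):
        a, _, _ = small_pair
        loci = define_loci(np.ones(len(a)), a, small_panel, LocusThresholds())
        assert loci == []


class TestPairwiseR2:
    def test_duplicated_column_r2_one(self):
        g = np.random.default_rng(1).integers(0, 3, size=(50, 2)).astype(float)
        g[:, 1] = g[:, 0]
        panel = LdPanel(
            snp=np.array(["a", "b"]), chrom=np.array(["1", "1"]),
            pos=np.array([1, 2]), block_id=np.zeros(2, int), genotypes=g,
        )
        tab = pairwise_r2(panel, ["a", "b"])
        assert tab.loc["a", "b"] == pytest.approx(1.0)

    def test_allele_flip_invariance(self):
        g = np.random.default_rng(2).integers(0, 3, size=(50, 2)).astype(float)
        g[:, 1] = 2 - g[:, 0]
        panel = LdPanel(
            snp=np.array(["a", "b"]), chrom=np.array(["1", "1"]),
            pos=np.array([1, 2]), block_id=np.zeros(2, int), genotypes=g,
        )
        assert pairwise_r2(panel, ["a", "b"]).loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        g = np.random.default_rng(3).integers(0, 3, size=(1000, 20)).astype(float)
        panel = LdPanel(
            snp=np.array([f"s{i}" for i in range(20)]),
            chrom=np.array(["1"] * 20), pos=np.arange(1, 21),
            block_id=np.zeros(20, int), genotypes=g,
        )
        tab = pairwise_r2(panel, [f"s{i}" for i in range(20)]).to_numpy()
        off = tab[np.triu_indices(20, k=1)]
        assert np.median(off) < 0.01

    def test_unknown_id_hard_error(self, small_panel):
        with pytest.raises(KeyError):
            pairwise_r2(small_panel, ["nope"])


def _locus(chrom, start, end, lead="x", fdr=0.01, label=""):
    return Locus(chrom, start, end, [lead], [lead], [lead], fdr, label)


class TestOverlap:
    def test_basic_overlap_and_merge(self):
        a = [_locus("1", 100, 200)]
        b = [_locus("1", 150, 300)]
        res = overlap_loci(a, b)
        assert res.pairs == [(0, 0)]
        merged = merge_unique_loci([a, b])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 300)

    def test_different_chromosomes_do_not_overlap(self):
        res = overlap_loci([_locus("1", 100, 200)], [_locus("2", 100, 200)])
        assert res.pairs == []
        assert res.only_a == [0] and res.only_b == [0]

    def test_three_analyses_chain_into_one_unique_locus(self):
        lists = [
            [_locus("1", 100, 200, label="A")],
            [_locus("1", 180, 320, label="B")],
            [_locus("1", 300, 400, label="C")],
        ]
        merged = merge_unique_loci(lists)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 400)
        assert merged[0].analysis_label == "A+B+C"

    def test_bookended_intervals_do_not_merge(self):
        # [100, 200] and [201, 300] share no base pair
        merged = merge_unique_loci(
            [[_locus("1", 100, 200)], [_locus("1", 201, 300)]]
        )
        assert len(merged) == 2


class TestConcordance:
    def test_nineteen_of_twenty_is_95_percent(self):
        rows_a, rows_b, loci = [], [], []
        for i in range(20):
            za = 3.0
            zb = 2.0 if i else -2.0  # first locus discordant
            rows_a.append((f"rs{i}", "1", 1000 + i, "A", "G", za))
            rows_b.append((f"rs{i}", "1", 1000 + i, "A", "G", zb))
            loci.append(_locus("1", 1000 + i, 1000 + i, lead=f"rs{i}"))
        table, frac, pct = effect_concordance(
            loci, make_sumstats(rows_a), make_sumstats(rows_b)
        )
        assert frac == pytest.approx(19 / 20)
        assert pct == 95

    def test_opposite_signs_discordant(self):
        a = make_sumstats([("rs1", "1", 100, "A", "G", 3.0)])
        b = make_sumstats([("rs1", "1", 100, "A", "G", -2.0)])
        table, _, _ = effect_concordance([_locus("1", 100, 100, "rs1")], a, b)
        assert table["status"].iloc[0] == "discordant"

    def test_zero_or_missing_z_indeterminate(self):
        a = make_sumstats([("rs1", "1", 100, "A", "G", 3.0)])
        b = make_sumstats([("rs1", "1", 100, "A", "G", 0.0)])
        loci = [_locus("1", 100, 100, "rs1"), _locus("1", 200, 200, "rs2")]
        table, frac, _ = effect_concordance(loci, a, b)
        assert list(table["status"]) == ["indeterminate", "indeterminate"]
        assert np.isnan(frac)
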
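"""Locus nomination: LD blocks, hotspot extension, wingspans, eQTL table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shscreen import (
    BlockStructure,
    GeneModel,
    LocusWindow,
    compute_r2,
    eqtl_window_comparison,
    extend_to_hotspots,
    ld_block,
    nominate_all,
    nominate_genes,
    simulate_genome_toy,
)
from shscreen.nominate import pad_window_to_fixed


class TestR2:
    def test_self_correlation_is_one(self):
        v = [0, 1, 2, 1, 0, 2]
        assert compute_r2(v, v) == pytest.approx(1.0)

    def test_zero_covariance_by_construction(self):
        assert compute_r2([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_matches_pearson_oracle(self):
        a, b = [0, 1, 2, 2, 0, 1], [0, 1, 2, 1, 0, 2]
        expected = stats.pearsonr(a, b).statistic ** 2
        assert compute_r2(a, b) == pytest.approx(expected)

    def test_monomorphic_is_nan_not_zero(self):
        assert np.isnan(compute_r2([1, 1, 1, 1], [0, 1, 2, 0]))

    def test_rejects_short_or_mismatched(self):
        with pytest.raises(ValueError):
            compute_r2([0, 1], [1, 0])
        with pytest.raises(ValueError):
            compute_r2([0, 1, 2], [0, 1])


class TestLdBlock:
    def test_sentinel_only_block(self):
        toy = simulate_genome_toy(2, seed=1)
        # kill LD by replacing all other columns with independent noise
        rng = np.random.default_rng(0)
        sid = toy.sentinels[0]
        for c in toy.dosages.columns:
            if c != sid:
                toy.dosages[c] = rng.integers(0, 3, len(toy.dosages))
        pos = int(toy.snps.loc[sid, "pos"])
        start, end = ld_block(sid, toy, 0.999)
        assert (start, end) == (pos, pos + 1)

    def test_perfect_copy_block_spans_all_copies(self):
        toy = simulate_genome_toy(
            2, block_structure=BlockStructure(flip_prob=0.0), seed=2
        )
        sid = toy.sentinels[0]
        block = toy.snps[toy.snps["locus"] == "L001"]
        start, end = ld_block(sid, toy, 0.8)
        assert start == block["pos"].min()
        assert end == block["pos"].max() + 1

    def test_matches_per_snp_brute_force(self):
        toy = simulate_genome_toy(4, block_structure=BlockStructure(flip_prob=0.1),
                                  seed=3)
        for sid in toy.sentinels:
            s = toy.dosages[sid]
            qual = [sid]
            for other in toy.dosages.columns:
                r2 = compute_r2(s, toy.dosages[other])
                if np.isfinite(r2) and r2 >= 0.8:
                    qual.append(other)
            pos = toy.snps.loc[sorted(set(qual)), "pos"]
            assert ld_block(sid, toy, 0.8) == (pos.min(), pos.max() + 1)

    def test_monomorphic_sentinel_errors(self):
        toy = simulate_genome_toy(2, seed=4)
        toy.dosages[toy.sentinels[0]] = 1
        with pytest.raises(ValueError, match="monomorphic"):
            ld_block(toy.sentinels[0], toy)


class TestHotspotExtension:
    HS = pd.DataFrame({"start": [100, 900], "end": [200, 1000]})

    def test_hand_interval_arithmetic(self):
        assert extend_to_hotspots((400, 500), self.HS, 2000) == (200, 900)

    def test_no_flanking_hotspot_hits_chromosome_ends(self):
        assert extend_to_hotspots((50, 80), self.HS.iloc[1:], 2000)[0] == 0
        assert extend_to_hotspots((1500, 1600), self.HS, 2000)[1] == 2000

    def test_immediately_flanking_hotspots_give_the_gap(self):
        assert extend_to_hotspots((200, 900), self.HS, 2000) == (200, 900)

    def test_block_outside_chromosome_errors(self):
        with pytest.raises(ValueError):
            extend_to_hotspots((400, 2500), self.HS, 2000)


def _window(start, end, locus="L001"):
    return LocusWindow(locus=locus, chrom="chr1", sentinel="rs1",
                       sentinel_pos=(start + end) // 2, ld_start=start,
                       ld_end=end, ext_start=start, ext_end=end)


class TestWingspan:
    def test_gene_inside_window_nominated(self):
        w = _window(1_000_000, 1_200_000)
        g = GeneModel("g1", "chr1", "+", 1_050_000, 1_060_000)
        assert nominate_genes(w, [g]) == ["g1"]

    def test_plus_strand_upstream_reach(self):
        w = _window(1_000_000, 1_200_000)
        g = GeneModel("g1", "chr1", "+", 1_200_000 + 105_000, 1_400_000)
        assert nominate_genes(w, [g]) == ["g1"]

    def test_strand_decides_at_105kb_left_of_window(self):
        w = _window(1_000_000, 1_200_000)
        minus = GeneModel("g1", "chr1", "-", 800_000, 1_000_000 - 105_000)
        plus = GeneModel("g1", "chr1", "+", 800_000, 1_000_000 - 105_000)
        assert nominate_genes(w, [minus]) == ["g1"]  # 110 kb reach past TSS
        assert nominate_genes(w, [plus]) == []  # only 40 kb past the end
        # strand-agnostic mode nominates both
        assert nominate_genes(w, [plus], strand_aware=False) == ["g1"]

    def test_exact_110kb_boundary_half_open(self):
        w = _window(1_000_000, 1_200_000)
        at = GeneModel("g", "chr1", "+", 1_200_000 + 110_000, 1_500_000)
        just_in = GeneModel("g", "chr1", "+", 1_200_000 + 110_000 - 1, 1_500_000)
        assert nominate_genes(w, [at]) == []
        assert nominate_genes(w, [just_in]) == ["g"]

    def test_monotone_in_wingspan(self, toy_panel):
        _, small = nominate_all(toy_panel, up_kb=110, down_kb=40)
        _, large = nominate_all(toy_panel, up_kb=150, down_kb=80)
        for locus, genes in small.assignments.items():
            assert set(genes) <= set(large.assignments[locus])

    def test_window_invariants(self, toy_panel):
        windows, _ = nominate_all(toy_panel)
        for w in windows:
            assert w.ext_start <= w.ld_start <= w.sentinel_pos < w.ld_end <= w.ext_end


def brute_force_nominate(panel, r2_threshold=0.8, up_kb=110, down_kb=40):
    """Independent oracle: test every SNP and every gene explicitly."""
    out = {}
    for i, sid in enumerate(panel.sentinels):
        s = panel.dosages[sid]
        positions = [int(panel.snps.loc[sid, "pos"])]
        for other in panel.dosages.columns:
            r2 = compute_r2(s, panel.dosages[other])
            if np.isfinite(r2) and r2 >= r2_threshold:
                positions.append(int(panel.snps.loc[other, "pos"]))
        lo, hi = min(positions), max(positions) + 1
        ext_lo, ext_hi = 0, panel.chrom_length
        for _, h in panel.hotspots.iterrows():
            if h.end <= lo:
                ext_lo = max(ext_lo, int(h.end))
            if h.start >= hi:
                ext_hi = min(ext_hi, int(h.start))
        genes = []
        for g, row in panel.genes.iterrows():
            up, down = int(up_kb * 1000), int(down_kb * 1000)
            if row.strand == "+":
                ws, we = max(0, row.txStart - up), row.txEnd + down
            else:
                ws, we = max(0, row.txStart - down), row.txEnd + up
            if ws < ext_hi and ext_lo < we:
                genes.append(g)
        out[f"L{i + 1:03d}"] = sorted(genes)
    return out


def test_nomination_matches_brute_force_oracle():
    for seed in range(5):
        toy = simulate_genome_toy(4, genes_per_locus=5, seed=seed)
        _, cand = nominate_all(toy)
        assert cand.assignments == brute_force_nominate(toy)


class TestEqtlComparison:
    def test_padding_is_symmetric_about_midpoint(self):
        assert pad_window_to_fixed(190_000, 210_000, 100_000) == (150_000, 250_000)
        assert pad_window_to_fixed(0, 10_000, 100_000) == (0, 100_000)

    @staticmethod
    def _setup_table(n_hit_in=3, n_nonhit_in=1, n_hit_out=1, n_nonhit_out=3):
        w = _window(1_000_000, 1_002_000)
        genes, eqtl, hits = [], [], []
        pos_in, pos_out = 1_000_500, 5_000_000
        idx = 0
        for n, inside, hit in [(n_hit_in, True, True), (n_nonhit_in, True, False),
                               (n_hit_out, False, True), (n_nonhit_out, False, False)]:
            for _ in range(n):
                name = f"g{idx}"
                idx += 1
                p = pos_in if inside else pos_out
                genes.append(GeneModel(name, "chr1", "+", p, p + 100))
                eqtl.append(name)
                if hit:
                    hits.append(name)
        return w, genes, eqtl, hits

    def test_balanced_table_enumeration(self):
        """Table [[3,1],[1,3]] has two-sided Fisher p = 34/70."""
        w, genes, eqtl, hits = self._setup_table()
        res = eqtl_window_comparison([w], genes, eqtl, hits)
        assert res["table"].tolist() == [[3, 1], [1, 3]]
        assert res["p_value"] == pytest.approx(34 / 70)

    def test_extreme_table_enumeration(self):
        """All hits nominated, no non-hit nominated: p = 2/70."""
        w, genes, eqtl, hits = self._setup_table(4, 0, 0, 4)
        res = eqtl_window_comparison([w], genes, eqtl, hits)
        assert res["p_value"] == pytest.approx(2 / 70)

    def test_null_p_roughly_uniform(self, rng):
        """Hits independent of nomination: p approximately uniform."""
        pvals = []
        for rep in range(200):
            w = _window(1_000_000, 1_002_000)
            genes, eqtl = [], []
            for i in range(40):
                inside = rng.random() < 0.5
                p = 1_000_500 if inside else 5_000_000
                genes.append(GeneModel(f"g{i}", "chr1", "+", p, p + 100))
                eqtl.append(f"g{i}")
            hits = list(rng.choice(eqtl, size=10, replace=False))
            pvals.append(eqtl_window_comparison([w], genes, eqtl, hits)["p_value"])
        # Fisher p is discrete and conservative; mean must not be depressed
        assert np.mean(pvals) > 0.45
        assert min(pvals) > 1e-4

    def test_empty_universe_errors(self):
        w, genes, _, hits = self._setup_table()
        with pytest.raises(ValueError):
            eqtl_window_comparison([w], genes, [], hits)
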
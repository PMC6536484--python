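"""Densities, overlaps, TSS profiles, enrichment, breadth, signal medians."""

import numpy as np
import pandas as pd
import pytest

import polyband as pb
from polyband import feature_stats as fs
from polyband.intervals import ChromosomeSpace
from polyband.structures import GeneModel

from conftest import boolean_cover, frame, random_intervals


def points(chrom, positions):
    return pd.DataFrame({"chrom": chrom, "pos": positions})


class TestDensity:
    def test_definition(self):
        table = fs.density(points("c", [10, 20, 30, 40, 50]),
                           {"s": frame("c", [(0, 2_500)])})
        assert table.iloc[0]["density_per_kb"] == pytest.approx(2.0)

    def test_zero_points(self):
        table = fs.density(points("c", []), {"s": frame("c", [(0, 1_000)])})
        assert table.iloc[0]["density_per_kb"] == 0.0

    def test_zero_length_set_is_null_with_warning(self):
        with pytest.warns(UserWarning, match="zero length"):
            table = fs.density(points("c", [5]), {"s": frame("c", [])})
        assert table.iloc[0]["density_per_kb"] is None

    def test_planted_bias_ranks_aquamarine_first(self, sim_default, segmented_default):
        cfg, genome, feats = sim_default
        domains, _ = segmented_default
        table = fs.density(feats.points["p_element"],
                           fs.state_region_sets(domains, cfg.target_chrom))
        table = table.set_index("set")["density_per_kb"]
        assert table.idxmax() == "aquamarine"
        assert all(table["aquamarine"] > table[s] for s in table.index if s != "aquamarine")


class TestOverlapPercent:
    def test_definition_and_empty(self):
        table = fs.overlap_percent(frame("c", [(0, 700)]), {"s": frame("c", [(0, 1_000)])})
        assert table.iloc[0]["percent"] == pytest.approx(70.0)
        table = fs.overlap_percent(frame("c", []), {"s": frame("c", [(0, 1_000)])})
        assert table.iloc[0]["percent"] == 0.0

    def test_matches_intersection_oracle(self):
        rng = np.random.default_rng(23)
        length = 100_000
        feats = random_intervals(rng, 200, length)
        regions = random_intervals(rng, 200, length)
        table = fs.overlap_percent(frame("c", feats), {"s": frame("c", regions)})
        mask_r = boolean_cover(regions, length)
        mask_f = boolean_cover(feats, length)
        assert table.iloc[0]["percent"] == pytest.approx(
            100.0 * (mask_r & mask_f).sum() / mask_r.sum())


class TestTSSProfile:
    SCOPE = frame("c", [(8_000, 12_000)])

    def test_plus_strand_coordinate_arithmetic(self):
        gene = GeneModel("g", "c", 10_000, 20_000, "+", 1)
        prof = fs.tss_profile(points("c", [9_900]), [gene], self.SCOPE)
        assert prof.as_series()["s1"] == 1 and prof.values.sum() == 1
        prof = fs.tss_profile(points("c", [10_100]), [gene], self.SCOPE)
        assert prof.as_series()["g1"] == 1

    def test_transcript_normalisation(self):
        gene = GeneModel("g", "c", 10_000, 20_000, "+", 2)
        prof = fs.tss_profile(points("c", [9_900]), [gene], self.SCOPE)
        assert prof.as_series()["s1"] == pytest.approx(0.5)

    def test_head_to_head_shared_spacer_credits_both(self):
        minus = GeneModel("gm", "c", 2_000, 10_001, "-", 1)   # TSS at 10,000
        plus = GeneModel("gp", "c", 10_300, 18_000, "+", 1)   # TSS at 10,300
        prof = fs.tss_profile(points("c", [10_150]), [minus, plus], self.SCOPE)
        assert prof.as_series()["s1"] == 2  # one feature, s1 of both genes

    def test_minus_strand_mirrored(self):
        gene = GeneModel("g", "c", 2_000, 10_001, "-", 1)  # five_prime_start 10,000
        prof = fs.tss_profile(points("c", [10_050]), [gene], self.SCOPE)
        assert prof.as_series()["s1"] == 1
        prof = fs.tss_profile(points("c", [9_950]), [gene], self.SCOPE)
        assert prof.as_series()["g1"] == 1

    def test_out_of_scope_gene_ignored(self):
        gene = GeneModel("g", "c", 50_000, 60_000, "+", 1)
        prof = fs.tss_profile(points("c", [49_900]), [gene], self.SCOPE)
        assert prof.n_genes == 0 and prof.values.sum() == 0

    def test_interval_features_binned_by_midpoint(self):
        gene = GeneModel("g", "c", 10_000, 20_000, "+", 1)
        iv = frame("c", [(9_850, 9_950)])  # midpoint 9,900 -> s1
        prof = fs.tss_profile(iv, [gene], self.SCOPE)
        assert prof.as_series()["s1"] == 1

    def test_total_mass_conservation(self, sim_default, segmented_default):
        cfg, genome, feats = sim_default
        _, structures = segmented_default
        scope = fs.structure_region_sets(structures)["interband"]
        prof = fs.tss_profile(feats.points["dhs"], genome.genes, scope)
        # per-gene brute-force counter over the full 2 x n_bins window
        total = 0.0
        pos = feats.points["dhs"]["pos"].to_numpy()
        scope_iv = list(pb.IntervalSet(scope))
        for g in genome.genes:
            if g.chrom != "chr4":
                continue
            p = g.five_prime_start
            if not any(iv.contains(g.chrom, p) for iv in scope_iv):
                continue
            b = p if g.strand == "+" else p + 1
            inside = (pos >= b - 1_000) & (pos < b + 1_000)
            total += inside.sum() / g.n_transcripts
        assert prof.values.sum() == pytest.approx(total)


class TestEnrichment:
    def test_rows_verdicts_and_flags(self):
        domains = pd.DataFrame({
            "chrom": ["t"] * 4 + ["r"] * 4,
            "start": [0, 100, 200, 300] * 2,
            "end": [100, 200, 300, 400] * 2,
            "state": ["aquamarine"] * 8,
        })
        feat = frame("t", [(0, 100)])
        space = ChromosomeSpace({"t": 400, "r": 400}, target="t")
        table = fs.wilcoxon_enrichment({"f": feat}, domains, space, alpha=0.5)
        aqua = table[table["state"] == "aquamarine"].iloc[0]
        assert aqua["n_target"] == 4 and aqua["n_rest"] == 4
        ruby = table[table["state"] == "ruby"].iloc[0]
        assert ruby["verdict"] == "ns" and ruby["flag"] == "insufficient_sample"

    def test_identical_coverage_is_ns(self):
        domains = pd.DataFrame({
            "chrom": ["t"] * 3 + ["r"] * 3,
            "start": [0, 200, 400] * 2,
            "end": [200, 400, 600] * 2,
            "state": ["ruby"] * 6,
        })
        feat = pd.DataFrame({"chrom": ["t", "r"], "start": [0, 0], "end": [100, 100]})
        space = ChromosomeSpace({"t": 600, "r": 600}, target="t")
        table = fs.wilcoxon_enrichment({"f": feat}, domains, space)
        row = table[table["state"] == "ruby"].iloc[0]
        assert row["verdict"] == "ns" and row["p_value"] == pytest.approx(1.0)

    def test_planted_enrichment_specific_to_target_open_states(self, sim_default):
        cfg, genome, feats = sim_default
        domains = genome.domains()
        table = fs.wilcoxon_enrichment(
            {"hp1a": feats.intervals["hp1a"], "pof": feats.intervals["pof"]},
            domains, genome.space)
        for _, row in table.iterrows():
            expected = "enriched" if row["state"] in ("aquamarine", "lazurite") else "ns"
            assert row["verdict"] == expected, row

    def test_fragment_unit_mode_runs(self, sim_default):
        cfg, genome, feats = sim_default
        domains = genome.domains()
        target_only = domains[domains["chrom"] == cfg.target_chrom]
        rest = domains[domains["chrom"] != cfg.target_chrom].head(200)
        table = fs.wilcoxon_enrichment(
            {"hp1a": feats.intervals["hp1a"]},
            pd.concat([target_only.head(100), rest]), genome.space, unit="fragment")
        assert (table["n_target"] > 100).any()  # fragments outnumber domains


class TestBreadth:
    def test_medians_and_direction(self, segmented_default):
        _, structures = segmented_default
        ib = next(s for s in structures if s.klass == "interband")
        band = next(s for s in structures if s.klass != "interband")
        genes = [
            GeneModel("a", "chr4", ib.start, ib.start + 500, "+", 1, 10),
            GeneModel("b", "chr4", ib.start + 600, ib.start + 900, "+", 1, 12),
            GeneModel("c", "chr4", band.start, band.start + 500, "+", 1, 2),
            GeneModel("d", "chr4", band.start + 600, band.start + 900, "+", 1, 4),
        ]
        summary, pairs = fs.expression_breadth_compare(genes, structures)
        med = summary.set_index("group")["median"]
        assert med["interband"] == 11 and med[band.klass] == 3

    def test_equal_breadths_p_one(self, segmented_default):
        _, structures = segmented_default
        ib = next(s for s in structures if s.klass == "interband")
        band = next(s for s in structures if s.klass != "interband")
        genes = [GeneModel("a", "chr4", ib.start, ib.start + 100, "+", 1, 5),
                 GeneModel("b", "chr4", band.start, band.start + 100, "+", 1, 5)]
        _, pairs = fs.expression_breadth_compare(genes, structures)
        row = pairs[(pairs["group_a"] == "interband") & (pairs["group_b"] == band.klass)]
        assert row["p_value"].iloc[0] == pytest.approx(1.0)

    def test_planted_ordering_recovered(self, sim_default, segmented_default):
        _, genome, _ = sim_default
        _, structures = segmented_default
        summary, _ = fs.expression_breadth_compare(genome.genes, structures)
        med = summary.set_index("group")["median"]
        assert med["interband"] > med["gray_band"] > med["black_band"]


class TestSignalMedian:
    def test_peak_is_max_and_median(self):
        signal = pd.DataFrame({"chrom": "c", "start": [0, 100], "end": [100, 200],
                               "value": [1.0, 3.0]})
        table = fs.domain_signal_median(signal, {"s": frame("c", [(50, 150)])})
        assert table.iloc[0]["median_peak"] == 3.0
        three = frame("c", [(0, 10), (100, 110), (300, 310)])
        signal = pd.DataFrame({"chrom": "c", "start": [0, 100, 300],
                               "end": [10, 110, 310], "value": [0.0, 2.0, 4.0]})
        assert fs.domain_signal_median(signal, {"s": three}).iloc[0]["median_peak"] == 2.0

    def test_empty_signal_gives_zero_peaks(self):
        table = fs.domain_signal_median(
            pd.DataFrame(columns=["chrom", "start", "end", "value"]),
            {"s": frame("c", [(0, 100)])})
        assert table.iloc[0]["median_peak"] == 0.0

    def test_planted_repressive_signal(self, sim_default, segmented_default):
        cfg, genome, feats = sim_default
        domains, structures = segmented_default
        per_state = fs.domain_signal_median(
            feats.signals["h3k27me3"], fs.state_region_sets(domains, cfg.target_chrom))
        med = per_state.set_index("set")["median_peak"]
        assert med.idxmax() == "ruby"
        members = {
            k: pd.concat([s.member_domains for s in structures if s.klass == k],
                         ignore_index=True)[["chrom", "start", "end"]]
            for k in ("interband", "gray_band", "black_band")
        }
        per_struct = fs.domain_signal_median(feats.signals["h3k27me3"], members,
                                             length_weighted=True)
        black = per_struct.set_index("set")["median_peak"]["black_band"]
        # ruby is a minority of band length, so the typical black-band base
        # sits in a domain with near-zero signal
        assert abs(black) < 1.0 < med["ruby"]
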
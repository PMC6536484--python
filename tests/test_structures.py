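"""Band/interband segmentation, inclusions, gene content, anchors."""

import pandas as pd
import pytest

from polyband.structures import (
    BLACK,
    GRAY,
    INTERBAND,
    GeneModel,
    apply_anchors,
    apply_overrides,
    check_alternation,
    classify_gene_content,
    find_inclusions,
    inclusions_to_frame,
    segment,
    structures_to_frame,
)


def domains(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


FIVE_DOMAIN_TRACK = domains([
    ("c", 0, 5_000, "aquamarine"),
    ("c", 5_000, 25_000, "lazurite"),
    ("c", 25_000, 30_000, "aquamarine"),
    ("c", 30_000, 70_000, "ruby"),
    ("c", 70_000, 80_000, "lazurite"),
    ("c", 80_000, 84_000, "aquamarine"),
])


class TestSegment:
    def test_alternating_hand_example(self):
        st = segment(FIVE_DOMAIN_TRACK)
        got = [(s.klass, s.start, s.end) for s in st]
        assert got == [
            (INTERBAND, 0, 5_000),
            (GRAY, 5_000, 25_000),
            (INTERBAND, 25_000, 30_000),
            (BLACK, 30_000, 80_000),  # ruby core plus attached lazurite edge
            (INTERBAND, 80_000, 84_000),
        ]
        assert check_alternation(st)

    def test_small_foreign_block_bridged_as_inclusion(self):
        st = segment(domains([
            ("c", 0, 5_000, "aquamarine"),
            ("c", 5_000, 9_000, "lazurite"),
            ("c", 9_000, 14_000, "aquamarine"),
        ]), inclusion_max=5_000)
        assert [(s.klass, s.start, s.end) for s in st] == [(INTERBAND, 0, 14_000)]
        assert [(i.state, i.size) for i in st[0].inclusions] == [("lazurite", 4_000)]

    def test_foreign_block_at_threshold_splits(self):
        st = segment(domains([
            ("c", 0, 5_000, "aquamarine"),
            ("c", 5_000, 10_000, "lazurite"),  # exactly inclusion_max: not bridged
            ("c", 10_000, 15_000, "aquamarine"),
        ]), inclusion_max=5_000)
        assert [s.klass for s in st] == [INTERBAND, GRAY, INTERBAND]

    def test_single_aquamarine_domain(self):
        st = segment(domains([("c", 0, 6_000, "aquamarine")]))
        assert [s.klass for s in st] == [INTERBAND]

    def test_short_aquamarine_becomes_band_inclusion(self):
        st = segment(domains([
            ("c", 0, 5_000, "aquamarine"),
            ("c", 5_000, 15_000, "lazurite"),
            ("c", 15_000, 16_000, "aquamarine"),  # 1 kb: below interband_min_len
            ("c", 16_000, 26_000, "lazurite"),
            ("c", 26_000, 31_000, "aquamarine"),
        ]))
        assert [s.klass for s in st] == [INTERBAND, GRAY, INTERBAND]
        band = st[1]
        assert [(i.state, i.size) for i in band.inclusions] == [("aquamarine", 1_000)]

    def test_no_aquamarine_single_band_with_warning(self):
        with pytest.warns(UserWarning, match="single band"):
            st = segment(domains([("c", 0, 10_000, "ruby"), ("c", 10_000, 14_000, "lazurite")]))
        assert len(st) == 1 and st[0].klass == BLACK

    def test_black_vs_gray_by_ruby_bases(self):
        base = [("c", 0, 5_000, "aquamarine"), ("c", 15_000, 20_000, "aquamarine")]
        gray = segment(domains(base + [("c", 5_000, 9_800, "ruby"),
                                       ("c", 9_800, 15_000, "lazurite")]), ruby_min=5_000)
        black = segment(domains(base + [("c", 5_000, 10_000, "ruby"),
                                        ("c", 10_000, 15_000, "lazurite")]), ruby_min=5_000)
        assert [s.klass for s in gray] == [INTERBAND, GRAY, INTERBAND]
        assert [s.klass for s in black] == [INTERBAND, BLACK, INTERBAND]

    def test_partition_no_overlap_every_base_assigned(self, segmented_default):
        domains_df, structures = segmented_default
        target = domains_df[domains_df["chrom"] == "chr4"]
        spans = sorted((s.start, s.end) for s in structures)
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))
        covered = sum(1 for row in target.itertuples()
                      if any(s <= row.start and row.end <= e for s, e in spans))
        assert covered == len(target)

    def test_raising_inclusion_max_never_adds_structures(self):
        track = FIVE_DOMAIN_TRACK
        counts = [len(segment(track, inclusion_max=m)) for m in (1_000, 5_000, 25_000)]
        assert counts == sorted(counts, reverse=True)

    def test_alternation_count_arithmetic(self, segmented_default):
        _, structures = segmented_default
        n_ib = sum(1 for s in structures if s.klass == INTERBAND)
        n_band = len(structures) - n_ib
        # both termini are bands on the default genome
        assert n_ib == n_band - 1


class TestInclusions:
    def test_single_record_summary(self):
        st = segment(domains([
            ("c", 0, 5_000, "aquamarine"),
            ("c", 5_000, 9_000, "lazurite"),
            ("c", 9_000, 14_000, "aquamarine"),
        ]))
        records, summary = find_inclusions(st)
        assert len(records) == 1 and records[0].size == 4_000
        row = summary.iloc[0]
        assert (row["count"], row["mean_bp"]) == (1, 4_000.0)

    def test_no_foreign_domains(self):
        st = segment(FIVE_DOMAIN_TRACK)
        records, summary = find_inclusions(st)
        assert records == [] and summary.empty

    def test_census_matches_generator_truth(self, sim_default, segmented_default):
        _, genome, _ = sim_default
        _, structures = segmented_default
        records, summary = find_inclusions(structures)
        got = inclusions_to_frame(records)[["state", "chrom", "start", "end"]] \
            .sort_values("start").reset_index(drop=True)
        want = genome.truth.inclusions.query("chrom == 'chr4'") \
            [["state", "chrom", "start", "end"]].sort_values("start").reset_index(drop=True)
        assert got.equals(want)
        for _, row in summary.iterrows():
            sizes = (want[want["state"] == row["state"]] if row["host_klass"] == INTERBAND
                     else want[want["state"] == "aquamarine"]).eval("end - start")
            sizes = sizes[sizes.index.isin(
                got[(got["state"] == row["state"])].index)]


class TestGeneContent:
    def test_tss_in_interband_body_in_band(self):
        st = segment(FIVE_DOMAIN_TRACK)
        gene = GeneModel("g1", "c", 4_800, 20_000, "+", 1)
        table, _ = classify_gene_content(st, [gene])
        ib = table[table["structure"] == st[0].name].iloc[0]
        band = table[table["structure"] == st[1].name].iloc[0]
        assert ib["n_5prime_starts"] == 1 and band["n_bodies"] == 1

    def test_whole_gene_and_polygenic(self):
        st = segment(FIVE_DOMAIN_TRACK)
        inside = GeneModel("g1", "c", 1_000, 3_000, "+", 1)
        b1 = GeneModel("g2", "c", 6_000, 12_000, "+", 1)
        b2 = GeneModel("g3", "c", 13_000, 20_000, "-", 1)
        table, summary = classify_gene_content(st, [inside, b1, b2])
        ib = table[table["structure"] == st[0].name].iloc[0]
        band = table[table["structure"] == st[1].name].iloc[0]
        assert ib["n_whole_genes"] == 1
        assert band["n_whole_genes"] == 2 and band["polygenic"]

    def test_gene_off_chromosome_skipped_with_warning(self):
        st = segment(FIVE_DOMAIN_TRACK)
        with pytest.warns(UserWarning, match="skipped"):
            table, _ = classify_gene_content(st, [GeneModel("g1", "chrX", 0, 100, "+", 1)])
        assert (table[["n_5prime_starts", "n_whole_genes", "n_bodies"]] == 0).all().all()

    def test_minus_strand_five_prime_start(self):
        g = GeneModel("g", "c", 100, 500, "-", 2)
        assert g.five_prime_start == 499


class TestAnchors:
    def test_join_assigns_name(self):
        st = segment(FIVE_DOMAIN_TRACK)
        anchors = pd.DataFrame({"chrom": ["c"], "pos": [2_500], "name": ["102B1-2/B3-4"]})
        st = apply_anchors(st, anchors)
        assert st[0].name == "102B1-2/B3-4"

    def test_anchor_in_unassigned_space_warns(self):
        st = segment(domains([("c", 0, 5_000, "aquamarine"),
                              ("c", 10_000, 20_000, "ruby"),
                              ("c", 20_000, 25_000, "aquamarine")]))
        anchors = pd.DataFrame({"chrom": ["c"], "pos": [7_000], "name": ["x"]})
        with pytest.warns(UserWarning, match="no structure"):
            apply_anchors(st, anchors)

    def test_conflicting_names_raise(self):
        st = segment(FIVE_DOMAIN_TRACK)
        anchors = pd.DataFrame({"chrom": ["c", "c"], "pos": [1_000, 2_000],
                                "name": ["a", "b"]})
        with pytest.raises(Exception, match="conflict"):
            apply_anchors(st, anchors)

    def test_truth_midpoint_anchors_name_all_structures(self, sim_default, segmented_default):
        _, genome, _ = sim_default
        _, structures = segmented_default
        anchors = genome.anchors[genome.anchors["chrom"] == "chr4"]
        named = apply_anchors(list(structures), anchors)
        truth = genome.truth.structures.query("chrom == 'chr4'")
        assert [s.name for s in named] == list(truth["name"])


class TestOverrides:
    def test_forced_class_coalesces_neighbours(self):
        st = segment(domains([
            ("c", 0, 5_000, "aquamarine"),
            ("c", 5_000, 15_000, "lazurite"),
            ("c", 15_000, 20_000, "aquamarine"),   # will be forced into a band
            ("c", 20_000, 30_000, "lazurite"),
            ("c", 30_000, 35_000, "aquamarine"),
        ]))
        target = st[2]
        assert target.klass == INTERBAND
        merged = apply_overrides(st, {target.name: GRAY})
        assert [s.klass for s in merged] == [INTERBAND, GRAY, INTERBAND]
        assert merged[1].start == 5_000 and merged[1].end == 30_000
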
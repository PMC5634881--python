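"""Interval annotation, proximity, intersection, permutation statistics, BED IO."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_intervals
from riberflow.containers import GeneModel
from riberflow.intervals import (
    BedFormatError,
    GenomeWorkspace,
    annotate_to_tss,
    count_overlaps,
    intersect_exact,
    permutation_overlap_test,
    proximity_pairs,
    read_bed,
    segment_enrichment,
    write_bed,
)

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def iv(*rows) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=BED_COLS)


class TestAnnotateToTss:
    models = [
        GeneModel("gA", "chr1", "+", [(10_000, 10_500), (11_000, 11_400)]),
        GeneModel("gB", "chr1", "-", [(50_000, 50_600), (51_000, 51_500)]),
    ]

    def test_peak_at_tss_is_promoter_distance_zero(self):
        peaks = iv(("chr1", 9_950, 10_050, "p1", 0, "."))
        out = annotate_to_tss(peaks, self.models)
        assert out.loc["p1", "tss_distance"] == 0
        assert out.loc["p1", "label"] == "promoter"

    def test_500_upstream_on_plus_strand_is_promoter(self):
        peaks = iv(("chr1", 9_450, 9_550, "p1", 0, "."))
        out = annotate_to_tss(peaks, self.models)
        assert out.loc["p1", "tss_distance"] == -500
        assert out.loc["p1", "label"] == "promoter"

    def test_150_downstream_is_outside_window(self):
        peaks = iv(("chr1", 10_100, 10_200, "p1", 0, "."))
        out = annotate_to_tss(peaks, self.models)
        assert out.loc["p1", "tss_distance"] == 150
        assert out.loc["p1", "label"] != "promoter"
        assert out.loc["p1", "label"] == "exonic"

    def test_minus_strand_upstream_sign_flip(self):
        # 300 bp to the right of a minus-strand TSS is upstream
        peaks = iv(("chr1", 51_750, 51_850, "p1", 0, "."))
        out = annotate_to_tss(peaks, self.models)
        assert out.loc["p1", "nearest_gene"] == "gB"
        assert out.loc["p1", "tss_distance"] == -300
        assert out.loc["p1", "label"] == "promoter"

    def test_intronic_and_intergenic_labels(self):
        peaks = iv(
            ("chr1", 10_700, 10_800, "in_intron", 0, "."),
            ("chr1", 30_000, 30_100, "between", 0, "."),
        )
        out = annotate_to_tss(peaks, self.models)
        assert out.loc["in_intron", "label"] == "intronic"
        assert out.loc["between", "label"] == "intergenic"

    def test_mirrored_genome_leaves_promoter_labels_invariant(self):
        size = 100_000
        mirrored_models = []
        for m in self.models:
            exons = sorted((size - e, size - s) for s, e in m.exons)
            strand = "-" if m.strand == "+" else "+"
            mirrored_models.append(GeneModel(m.gene_id, "chr1", strand, exons))
        peaks = iv(("chr1", 9_450, 9_550, "p1", 0, "."))
        mirrored_peaks = iv(("chr1", size - 9_550, size - 9_450, "p1", 0, "."))
        a = annotate_to_tss(peaks, self.models)
        b = annotate_to_tss(mirrored_peaks, mirrored_models)
        assert a.loc["p1", "label"] == b.loc["p1", "label"]
        assert a.loc["p1", "tss_distance"] == b.loc["p1", "tss_distance"]


class TestProximityPairs:
    def test_identical_intervals_pair_at_distance_zero(self):
        a = iv(("chr1", 100, 200, "a1", 0, "."))
        out = proximity_pairs(a, a.assign(name="b1"))
        assert len(out) == 1 and out.loc[0, "distance"] == 0

    @pytest.mark.parametrize("gap,paired", [(1000, True), (1001, False)])
    def test_window_boundary_inclusive(self, gap, paired):
        a = iv(("chr1", 0, 100, "a1", 0, "."))       # midpoint 50
        b = iv(("chr1", gap, 100 + gap, "b1", 0, "."))  # midpoint 50+gap
        out = proximity_pairs(a, b, window=1000)
        assert (len(out) == 1) is paired

    def test_one_a_can_pair_with_many_b(self):
        a = iv(("chr1", 500, 600, "a1", 0, "."))
        b = iv(("chr1", 400, 500, "b1", 0, "."), ("chr1", 600, 700, "b2", 0, "."))
        out = proximity_pairs(a, b)
        assert len(out) == 2 and out["name_a"].nunique() == 1


def brute_force_pairs(a: pd.DataFrame, b: pd.DataFrame) -> set:
    hits = set()
    for _, x in a.iterrows():
        for _, y in b.iterrows():
            if x["chrom"] == y["chrom"] and x["start"] < y["end"] and y["start"] < x["end"]:
                hits.add((x["name"], y["name"]))
    return hits


class TestIntersectExact:
    def test_one_bp_overlap_counts(self):
        a = iv(("chr1", 0, 100, "a", 0, "."))
        b = iv(("chr1", 99, 200, "b", 0, "."))
        assert len(intersect_exact(a, b)) == 1

    def test_book_ended_half_open_is_no_overlap(self):
        a = iv(("chr1", 0, 100, "a", 0, "."))
        b = iv(("chr1", 100, 200, "b", 0, "."))
        assert len(intersect_exact(a, b)) == 0

    def test_matches_quadratic_oracle_and_intervaltree(self):
        from intervaltree import IntervalTree

        rng = np.random.default_rng(8)
        chroms = {"chr1": 10_000, "chr2": 8_000}
        a = random_intervals(rng, 50, chroms, "a")
        b = random_intervals(rng, 50, chroms, "b")
        got = set(map(tuple, intersect_exact(a, b).to_numpy()))
        assert got == brute_force_pairs(a, b)
        assert count_overlaps(a, b) == len(got)
        # independent library cross-check
        trees = {c: IntervalTree() for c in chroms}
        for _, y in b.iterrows():
            trees[y["chrom"]].addi(y["start"], y["end"], y["name"])
        via_tree = {
            (x["name"], hit.data)
            for _, x in a.iterrows()
            for hit in trees[x["chrom"]].overlap(x["start"], x["end"])
        }
        assert got == via_tree


class TestPermutationOverlapTest:
    workspace = GenomeWorkspace(lengths={"chr1": 50_000, "chr2": 40_000})

    def test_self_overlap_attains_plus_one_floor(self):
        rng = np.random.default_rng(1)
        a = random_intervals(rng, 30, self.workspace.lengths, "a", max_len=50)
        res = permutation_overlap_test(a, a, self.workspace, n_sims=199, seed=0)
        assert res["p_value"] == pytest.approx(1 / 200)
        assert res["observed"] >= 30

    def test_p_value_never_zero_and_null_mean_reported(self):
        rng = np.random.default_rng(2)
        a = random_intervals(rng, 10, self.workspace.lengths, "a")
        b = random_intervals(rng, 10, self.workspace.lengths, "b")
        res = permutation_overlap_test(a, b, self.workspace, n_sims=99, seed=3)
        assert res["p_value"] > 0
        assert res["null_mean"] >= 0

    def test_interval_longer_than_chromosome_raises(self):
        a = iv(("chr1", 0, 60_000, "a", 0, "."))
        with pytest.raises(ValueError, match="longer than its chromosome"):
            permutation_overlap_test(a, a, self.workspace, n_sims=5, seed=0)

    def test_planted_colocalization_detected(self):
        from riberflow.simulate import SimConfig, simulate_interval_sets

        cfg = SimConfig(seed=5, coloc_fraction=0.5)
        ref, query, _ = simulate_interval_sets(cfg, n_reference=300, n_query=300)
        ws = GenomeWorkspace(lengths=cfg.genome_lengths)
        res = permutation_overlap_test(query, ref, ws, n_sims=999, seed=5)
        assert res["p_value"] < 0.01


class TestSegmentEnrichment:
    def make_workspace(self):
        # one class covering 10% of a single 100 kb chromosome
        segments = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 10_000],
             "end": [10_000, 100_000], "label": ["target", "rest"]}
        )
        return GenomeWorkspace(lengths={"chr1": 100_000}, segments=segments)

    def test_all_peaks_inside_small_class_fold_about_ten(self):
        ws = self.make_workspace()
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 9_800, size=40)
        peaks = iv(*[("chr1", int(s), int(s) + 200, f"p{i}", 0, ".")
                     for i, s in enumerate(starts)])
        out = segment_enrichment(peaks, ws, n_sims=400, seed=1)
        assert out.loc["target", "fold"] == pytest.approx(10.0, rel=0.25)
        assert out.loc["target", "enriched"]

    def test_uniform_peaks_fold_near_one(self):
        ws = self.make_workspace()
        rng = np.random.default_rng(6)
        starts = rng.integers(0, 99_000, size=120)
        peaks = iv(*[("chr1", int(s), int(s) + 100, f"p{i}", 0, ".")
                     for i, s in enumerate(starts)])
        out = segment_enrichment(peaks, ws, n_sims=400, seed=2)
        assert out.loc["rest", "fold"] == pytest.approx(1.0, abs=0.1)
        assert not out.loc["rest", "enriched"]

    def test_absent_class_fold_is_nan_never_infinite(self):
        segments = pd.DataFrame(
            {"chrom": ["chr2"], "start": [0], "end": [1_000], "label": ["ghost"]}
        )
        ws = GenomeWorkspace(lengths={"chr1": 100_000, "chr2": 2_000},
                             segments=segments)
        peaks = iv(("chr1", 0, 100, "p1", 0, "."))
        out = segment_enrichment(peaks, ws, n_sims=50, seed=0)
        assert np.isnan(out.loc["ghost", "fold"])


class TestBedIO:
    def test_round_trip_is_byte_stable(self, tmp_path):
        rng = np.random.default_rng(7)
        original = random_intervals(rng, 25, {"chr1": 5_000}, "x")
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(original, p1)
        write_bed(read_bed(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_interval_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\tok\t0\t.\nchr1\t500\t400\tbad\t0\t.\n")
        with pytest.raises(BedFormatError, match=":2:"):
            read_bed(p)

    def test_track_header_skipped_with_warning(self, tmp_path):
        p = tmp_path / "h.bed"
        p.write_text('track name="x"\nchr1\t0\t100\ta\t0\t.\n')
        with pytest.warns(UserWarning, match="header"):
            out = read_bed(p)
        assert len(out) == 1

    def test_coordinate_beyond_workspace_is_fatal(self, tmp_path):
        p = tmp_path / "oob.bed"
        p.write_text("chr1\t0\t9999\ta\t0\t.\n")
        ws = GenomeWorkspace(lengths={"chr1": 5_000})
        with pytest.raises(BedFormatError, match="beyond"):
            read_bed(p, workspace=ws)
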
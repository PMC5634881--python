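"""Generator determinism, planted-truth invariants, structural checks."""

import numpy as np
import pandas as pd
import pytest

from riberflow.simulate import (
    DEFAULT_BIOTYPE_PROBS,
    SimConfig,
    SimConfigError,
    SimTruth,
    read_gtf,
    simulate_gene_models,
    simulate_interval_sets,
    simulate_lfq_matrix,
    simulate_nascent_counts,
    simulate_rip_counts,
    write_gtf,
)


class TestSimConfig:
    @pytest.mark.parametrize(
        "field,value",
        [("enriched_fraction", 1.2), ("coloc_fraction", -0.1),
         ("baseline_mean", 0.0), ("n_genes", 0), ("genome_lengths", {})],
    )
    def test_invalid_configurations_rejected(self, field, value):
        with pytest.raises(SimConfigError):
            SimConfig(**{field: value})

    def test_truth_round_trips_through_json(self, tmp_path):
        truth = SimTruth(
            enriched_ids={"case": {"g1", "g2"}},
            ir_shifted_introns={"g1:intron_0": 1.5},
            reverted_introns=["g1:intron_0"],
            coloc_pairs=[("q1", "r1")],
            bait_dependent_proteins=["p1"],
        )
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SimTruth.from_json(path)
        assert back.enriched_ids["case"] == {"g1", "g2"}
        assert back.coloc_pairs == [("q1", "r1")]


class TestDeterminism:
    def test_fixed_seed_reproduces_every_generator(self):
        cfg = SimConfig(seed=1, n_genes=60)
        m1, t1 = simulate_rip_counts(cfg)
        m2, t2 = simulate_rip_counts(cfg)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)
        assert t1.enriched_ids == t2.enriched_ids

        g1 = simulate_gene_models(cfg, n_genes=40)
        g2 = simulate_gene_models(cfg, n_genes=40)
        assert [(m.gene_id, m.exons, m.biotype) for m in g1] == [
            (m.gene_id, m.exons, m.biotype) for m in g2
        ]

        n1, _ = simulate_nascent_counts(cfg, g1)
        n2, _ = simulate_nascent_counts(cfg, g1)
        pd.testing.assert_frame_equal(n1.counts, n2.counts)

        r1, q1, _ = simulate_interval_sets(cfg, n_reference=30, n_query=30)
        r2, q2, _ = simulate_interval_sets(cfg, n_reference=30, n_query=30)
        pd.testing.assert_frame_equal(q1, q2)

        l1, _ = simulate_lfq_matrix(cfg, n_proteins=40)
        l2, _ = simulate_lfq_matrix(cfg, n_proteins=40)
        pd.testing.assert_frame_equal(l1, l2)

    def test_different_seeds_differ(self):
        m1, _ = simulate_rip_counts(SimConfig(seed=1, n_genes=50))
        m2, _ = simulate_rip_counts(SimConfig(seed=2, n_genes=50))
        assert not m1.counts.equals(m2.counts)


class TestRipCounts:
    def test_design_structure(self, rip_dataset):
        m, _ = rip_dataset
        assert set(m.design["cell_line"]) == {"case", "control"}
        assert set(m.design["fraction"]) == {"input", "IP"}
        assert m.counts.shape == (1000, 12)

    def test_truth_subset_of_generated_ids(self, rip_dataset):
        m, truth = rip_dataset
        for ids in truth.enriched_ids.values():
            assert ids <= set(m.counts.index)

    def test_null_configuration_has_empty_truth(self):
        _, truth = simulate_rip_counts(
            SimConfig(seed=0, n_genes=50, enriched_fraction=0.0)
        )
        assert truth.enriched_ids["case"] == set()

    def test_planted_effect_visible_in_raw_means(self):
        cfg = SimConfig(seed=3, n_genes=400, enrichment_log2fc=3.0,
                        background_ef_sigma=0.0)
        m, truth = simulate_rip_counts(cfg)
        ip = m.counts[m.samples_where(cell_line="case", fraction="IP")].mean(axis=1)
        inp = m.counts[m.samples_where(cell_line="case", fraction="input")].mean(axis=1)
        enriched = sorted(truth.enriched_ids["case"])
        obs = np.log2(ip[enriched] / inp[enriched])
        # depth factors differ between fractions; compare against the bulk
        null_shift = np.median(np.log2((ip + 1) / (inp + 1)).drop(enriched))
        assert (obs.mean() - null_shift) == pytest.approx(3.0, abs=0.2)


class TestGeneModels:
    def test_structural_invariants(self):
        cfg = SimConfig(seed=2)
        models = simulate_gene_models(cfg, n_genes=80)
        by_chrom = {}
        for m in models:
            exons = m.merged_exons
            assert all(s < e for s, e in exons)
            assert all(exons[i][1] < exons[i + 1][0] for i in range(len(exons) - 1))
            assert len(m.exons) >= 2
            assert m.end <= cfg.genome_lengths[m.chromosome]
            by_chrom.setdefault(m.chromosome, []).append((m.start, m.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))

    def test_intron_definition(self):
        models = simulate_gene_models(SimConfig(seed=2), n_genes=10)
        for m in models:
            exons = m.merged_exons
            assert len(m.introns) == len(exons) - 1
            for k, intron in enumerate(m.introns):
                assert intron == (exons[k][1], exons[k + 1][0])

    def test_biotype_frequencies_match_configured_distribution(self):
        cfg = SimConfig(seed=7, genome_lengths={"chr1": 150_000_000})
        models = simulate_gene_models(cfg, n_genes=10_000)
        freqs = pd.Series([m.biotype for m in models]).value_counts(normalize=True)
        for cls, p in DEFAULT_BIOTYPE_PROBS.items():
            assert freqs.get(cls, 0.0) == pytest.approx(p, abs=0.02)

    def test_gene_longer_than_every_chromosome_rejected(self):
        cfg = SimConfig(seed=0, genome_lengths={"chr1": 900})
        with pytest.raises(SimConfigError, match="does not fit"):
            simulate_gene_models(cfg, n_genes=3)

    def test_gtf_round_trip(self, tmp_path):
        models = simulate_gene_models(SimConfig(seed=4), n_genes=15)
        path = tmp_path / "models.gtf"
        write_gtf(models, path)
        back = {m.gene_id: m for m in read_gtf(path)}
        for m in models:
            assert back[m.gene_id].exons == m.exons
            assert back[m.gene_id].strand == m.strand
            assert back[m.gene_id].biotype == m.biotype


class TestNascentCounts:
    def test_truth_invariants(self):
        cfg = SimConfig(seed=5, n_genes=100, enriched_fraction=0.2)
        models = simulate_gene_models(cfg, n_genes=100)
        nm, truth = simulate_nascent_counts(cfg, models)
        shifted = set(truth.ir_shifted_introns)
        assert set(truth.reverted_introns) <= shifted
        assert shifted <= set(nm.counts.index)
        signs = np.sign(list(truth.ir_shifted_introns.values()))
        assert {-1.0, 1.0} == set(signs)

    def test_per_sign_reversal_fractions(self):
        cfg = SimConfig(seed=5, n_genes=300, enriched_fraction=0.3,
                        reversal_fraction=0.8, reversal_fraction_positive=0.4)
        models = simulate_gene_models(cfg, n_genes=300)
        _, truth = simulate_nascent_counts(cfg, models)
        rev = set(truth.reverted_introns)
        neg = [k for k, v in truth.ir_shifted_introns.items() if v < 0]
        pos = [k for k, v in truth.ir_shifted_introns.items() if v > 0]
        assert len(rev & set(neg)) / len(neg) == pytest.approx(0.8, abs=0.01)
        assert len(rev & set(pos)) / len(pos) == pytest.approx(0.4, abs=0.01)

    def test_counts_scale_with_feature_length(self):
        cfg = SimConfig(seed=6, n_genes=150, enriched_fraction=0.0)
        models = simulate_gene_models(cfg, n_genes=150)
        nm, _ = simulate_nascent_counts(cfg, models)
        lengths = nm.counts.attrs["lengths"]
        exons = [i for i in nm.counts.index if ":exon_" in i]
        density = nm.counts.loc[exons].sum(axis=1) / lengths[exons]
        long = lengths[exons] > lengths[exons].median()
        # per-bp density is length-independent, total counts are not
        assert density[long].median() == pytest.approx(
            density[~long].median(), rel=0.25
        )


class TestIntervalSets:
    def test_full_colocalization_every_query_near_a_reference(self):
        cfg = SimConfig(seed=8, coloc_fraction=1.0)
        ref, query, truth = simulate_interval_sets(
            cfg, n_reference=50, n_query=50, coloc_distance=0
        )
        from riberflow.intervals import proximity_pairs

        pairs = proximity_pairs(query, ref, window=1000)
        assert pairs["name_a"].nunique() == 50
        assert len(truth.coloc_pairs) == 50

    def test_planted_pair_count_binomial(self):
        cfg = SimConfig(seed=9, coloc_fraction=0.5)
        _, query, truth = simulate_interval_sets(cfg, n_reference=500, n_query=1000)
        assert len(truth.coloc_pairs) == 500
        assert query["name"].nunique() == 1000

    def test_intervals_respect_workspace_bounds(self):
        cfg = SimConfig(seed=10)
        ref, query, _ = simulate_interval_sets(cfg, n_reference=200, n_query=200)
        for df in (ref, query):
            for chrom, grp in df.groupby("chrom"):
                assert (grp["start"] >= 0).all()
                assert (grp["end"] <= cfg.genome_lengths[chrom]).all()


class TestLfqMatrix:
    def test_bait_present_in_all_replicates(self):
        lfq, _ = simulate_lfq_matrix(SimConfig(seed=11), missing_rate=0.3)
        assert lfq.loc["ESR2"].notna().all()

    def test_planted_reduction_in_knockdown_arm(self):
        lfq, truth = simulate_lfq_matrix(
            SimConfig(seed=12), noise_sigma=0.01, missing_rate=0.0,
            reduction_log2fc=2.0,
        )
        dep = truth.bait_dependent_proteins
        nt = lfq.filter(like="NT").loc[dep].mean(axis=1)
        kd = lfq.filter(like="shKD").loc[dep].mean(axis=1)
        # per-column handling efficiencies add spread; the median ratio
        # still centers on the planted 4-fold reduction
        assert np.median(np.log2(nt / kd)) == pytest.approx(2.0, abs=0.5)

    def test_bait_missing_raises_documented_error(self):
        from riberflow.proteomics import BaitError, bait_normalize

        lfq, _ = simulate_lfq_matrix(SimConfig(seed=13), n_proteins=20)
        lfq.loc["ESR2", "NT_r2"] = np.nan
        with pytest.raises(BaitError, match="NT_r2"):
            bait_normalize(lfq, "ESR2")
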
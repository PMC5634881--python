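"""End-to-end orchestration: demo run, input validation, report arithmetic.

``run_demo`` chains the full synthetic pipeline — simulate, enrich, select,
quantify retention, reversal, co-localize, interactome — on one seed and
writes every stage artifact plus a deterministic JSON report.  Re-running
with an unchanged configuration is a no-op unless forced (the report
carries the config hash).
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import config_hash, dump_json, percent
from .containers import CountMatrix
from .enrichment import enrichment_test
from .intervals import (
    GenomeWorkspace,
    permutation_overlap_test,
    proximity_pairs,
    read_bed,
    write_bed,
)
from .proteomics import bait_normalize, dependence_summary, permutation_fdr_test
from .rip import SelectionParams, biotype_enrichment, run_selection
from .simulate import (
    SimConfig,
    simulate_gene_models,
    simulate_interval_sets,
    simulate_lfq_matrix,
    simulate_nascent_counts,
    simulate_rip_counts,
    write_gtf,
)
from .splicing import differential_retention, retention_coefficients, reversal_analysis

log = logging.getLogger("riberflow")


def fraction_summary(k: int, n: int, what: str = "") -> dict:
    """Count/denominator/percent record used throughout reports.

    Percentages are integers, rounded half-up.
    """
    return {"what": what, "count": int(k), "of": int(n), "percent": percent(k, n)}


def trend_overlap_summary(n_up: int, n_down: int, n_total: int) -> dict:
    """Common-trend accounting: up + down regulated in both arms over the
    number regulated in the reference arm."""
    common = int(n_up) + int(n_down)
    return {
        "n_up": int(n_up),
        "n_down": int(n_down),
        "n_common_trend": common,
        "of": int(n_total),
        "percent": percent(common, n_total),
    }


class InputValidationError(ValueError):
    """Fatal schema problem in a pipeline input file."""


def validate_counts_design(counts_path, design_path) -> list[str]:
    """Schema diagnostics for a counts/design TSV pair (empty = clean)."""
    diags: list[str] = []
    try:
        CountMatrix.read_tsv(counts_path, design_path)
    except Exception as exc:  # surface every failure as a diagnostic
        diags.append(str(exc))
    return diags


def validate_bed(path, workspace: GenomeWorkspace | None = None) -> list[str]:
    """Schema diagnostics for a BED file (empty = clean)."""
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            read_bed(path, workspace=workspace)
    except Exception as exc:
        return [str(exc)]
    return []


def _ir_by_condition(nm: CountMatrix, lengths: pd.Series) -> dict[str, pd.DataFrame]:
    out = {}
    for cond in nm.design["condition"].unique():
        cols = nm.samples_where(condition=cond)
        out[cond] = retention_coefficients(nm.counts[cols], lengths)
    return out


def run_demo(
    seed: int,
    outdir: str | Path,
    cfg: SimConfig | None = None,
    force: bool = False,
    n_sims_overlap: int = 1000,
) -> dict:
    """Full synthetic pipeline on one seed; returns the run report.

    Writes stage artifacts (counts, enrichment tables, selection audit,
    retention tables, BED files, LFQ tables) and ``report.json`` under
    ``outdir``.  Fixed seed and config give byte-identical outputs.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or SimConfig(
        seed=seed,
        n_genes=400,
        genome_lengths={"chr1": 3_000_000, "chr2": 2_500_000},
    )
    if cfg.seed != seed:
        cfg = SimConfig(**{**cfg.to_dict(), "seed": seed})
    chash = config_hash(cfg.to_dict())

    report_path = outdir / "report.json"
    if report_path.exists() and not force:
        old = json.loads(report_path.read_text())
        if old.get("config_hash") == chash:
            log.info("config unchanged (%s); skipping (use force=True)", chash)
            return old

    report: dict = {"seed": seed, "config_hash": chash, "config": cfg.to_dict()}

    # --- RIP track -------------------------------------------------------
    m, truth = simulate_rip_counts(cfg)
    m.write_tsv(outdir / "rip_counts.tsv", outdir / "rip_design.tsv")
    truth.to_json(outdir / "rip_truth.json")
    case_tab = enrichment_test(m.subset_samples(m.samples_where(cell_line="case")))
    ctrl_tab = enrichment_test(m.subset_samples(m.samples_where(cell_line="control")))
    case_tab.to_csv(outdir / "enrichment_case.tsv", sep="\t")
    ctrl_tab.to_csv(outdir / "enrichment_control.tsv", sep="\t")
    audit, sel_report = run_selection(case_tab, ctrl_tab, SelectionParams())
    audit.to_csv(outdir / "rip_selection.tsv", sep="\t")
    selected = set(audit.index[audit["selected"]])
    planted = truth.enriched_ids["case"]
    report["rip"] = {
        **sel_report.to_dict(),
        "truth_recovery": fraction_summary(
            len(selected & planted), len(planted), "planted enriched RNAs selected"
        ),
    }

    # biotype classification of the selected set
    models = simulate_gene_models(cfg, n_genes=cfg.n_genes)
    write_gtf(models, outdir / "gene_models.gtf")
    background = pd.DataFrame(
        {"biotype": [md.biotype for md in models]},
        index=pd.Index([md.gene_id for md in models], name="feature_id"),
    )
    bio = biotype_enrichment(sorted(selected), background)
    bio.to_csv(outdir / "biotype_enrichment.tsv", sep="\t", index=False)
    report["biotypes"] = {
        row["biotype"]: round(float(row["fraction"]), 4) for _, row in bio.iterrows()
    }

    # --- nascent splicing track -----------------------------------------
    ncfg = SimConfig(
        **{
            **cfg.to_dict(),
            "enriched_fraction": 0.2,
            "ir_shift_log2": 2.5,
        }
    )
    nm, ntruth = simulate_nascent_counts(ncfg, models)
    nm.write_tsv(outdir / "nascent_counts.tsv", outdir / "nascent_design.tsv")
    ntruth.to_json(outdir / "nascent_truth.json")
    lengths = nm.counts.attrs["lengths"]
    ir = _ir_by_condition(nm, lengths)
    er_events = differential_retention(ir["er"], ir["wt"])
    er_events.to_csv(outdir / "retention_er_vs_wt.tsv", sep="\t")
    sig = er_events[er_events["significant"]]
    kd_events = differential_retention(
        ir["er_kd"].loc[sig.index], ir["er"].loc[sig.index]
    )
    rev = reversal_analysis(sig, kd_events)
    rev.to_csv(outdir / "reversal_by_bin.tsv", sep="\t")
    report["splicing"] = {
        "n_introns": int(len(er_events)),
        "n_significant": int(len(sig)),
        "reversal_by_bin": {
            str(b): (None if np.isnan(r["fraction_reverted"]) else round(float(r["fraction_reverted"]), 4))
            for b, r in rev.iterrows()
        },
    }

    # --- interval statistics track --------------------------------------
    ref, query, ivtruth = simulate_interval_sets(cfg, n_reference=200, n_query=200)
    write_bed(ref, outdir / "reference_sites.bed")
    write_bed(query, outdir / "query_sites.bed")
    ivtruth.to_json(outdir / "interval_truth.json")
    workspace = GenomeWorkspace(lengths=cfg.genome_lengths)
    pairs = proximity_pairs(query, ref, window=1000)
    overlap = permutation_overlap_test(
        query, ref, workspace, n_sims=n_sims_overlap, seed=seed
    )
    report["intervals"] = {
        "n_proximity_pairs": int(len(pairs)),
        "n_distinct_query_paired": int(pairs["name_a"].nunique()),
        "overlap_test": overlap,
    }

    # --- interactome track ----------------------------------------------
    lfq, ltruth = simulate_lfq_matrix(cfg)
    lfq.to_csv(outdir / "lfq_matrix.tsv", sep="\t")
    ltruth.to_json(outdir / "lfq_truth.json")
    norm = bait_normalize(lfq, "ESR2")
    nt_cols = [c for c in norm.columns if c.startswith("NT")]
    kd_cols = [c for c in norm.columns if c.startswith("shKD")]
    diff = permutation_fdr_test(
        norm, kd_cols, nt_cols, fdr_cut=0.01, seed=seed, bait_id="ESR2"
    )
    diff.to_csv(outdir / "interactome_diff.tsv", sep="\t")
    dep = dependence_summary(diff)
    planted_dep = set(ltruth.bait_dependent_proteins)
    called = set(diff.index[diff["significant"] & (diff["log2_ratio"] < 0)])
    report["interactome"] = {
        "dependence": dep,
        "planted_sensitivity": fraction_summary(
            len(called & planted_dep), len(planted_dep), "planted reductions called"
        ),
    }

    elapsed = time.time() - t0
    log.info("demo seed=%d finished in %.1fs", seed, elapsed)
    print(f"demo: seed={seed} elapsed={elapsed:.1f}s -> {report_path}", file=sys.stderr)
    dump_json(report, report_path)
    return report
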
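"""Intron-retention quantification and knock-down reversal analysis.

The intron retention coefficient (IR) of an intron in a sample is the
read density of the intron (reads per bp) divided by the pooled read
density over all exons of its gene — near 0 for a fully spliced intron,
near 1 for unspliced-like coverage.  Differential retention between
conditions is a per-intron Welch t-test on replicate IR values with BH
adjustment; the cross-condition *modulation coefficient* is the log2 ratio
of mean IRs (positive = reduced splicing efficiency in the first
condition).  The reversal analysis bins significant receptor-driven
events by their modulation coefficient and asks, per bin, what fraction
flips sign (significantly, by default) under the knock-down contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneModel
from .enrichment import bh_adjust

#: modulation-coefficient bins; half-open on the real line, labels as printed
BIN_EDGES = [-np.inf, -2.0, -1.5, 1.5, 2.0, np.inf]
BIN_LABELS = ["<-2", "[-2,-1.5)", "(-1.5,1.5)", "[1.5,2]", ">2"]


def extract_introns(model: GeneModel) -> list[tuple[int, int]]:
    """Intron intervals: complement of merged exons within the gene span."""
    return model.introns


def bin_label(x: float) -> str:
    """Bin a modulation coefficient; bins partition the real line."""
    if np.isnan(x):
        return "na"
    idx = int(np.digitize([x], BIN_EDGES[1:-1], right=False)[0])
    # digitize boundaries: x < -2 -> 0; -2 <= x < -1.5 -> 1; -1.5 <= x < 1.5 -> 2;
    # 1.5 <= x < 2 -> 3; x >= 2 -> 4.  The printed bins close [1.5,2] and open
    # >2, so move x == 2.0 down into the closed bin.
    if x == 2.0:
        idx = 3
    return BIN_LABELS[idx]


def _parse_feature_ids(index: pd.Index) -> pd.DataFrame:
    parts = index.str.rsplit(":", n=1)
    gene = parts.str[0]
    feat = parts.str[1]
    return pd.DataFrame(
        {"gene": gene, "kind": feat.str.split("_").str[0]}, index=index
    )


def retention_coefficients(
    counts: pd.DataFrame, lengths: pd.Series
) -> pd.DataFrame:
    """Per-intron IR values for every sample of a feature count table.

    ``counts`` rows are keyed ``gene:exon_k`` / ``gene:intron_k``;
    ``lengths`` gives each feature's bp length.  For each gene and sample,
    exon density = total exon reads / total exon bp; each intron's IR is
    (intron reads / intron bp) / exon density.  Genes with zero exon
    signal in a sample get NaN IR for their introns in that sample (the
    coefficient is undefined there); an intron with zero reads has IR 0.
    """
    meta = _parse_feature_ids(counts.index)
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:3]
        raise ValueError(f"missing lengths for features like {missing}")

    exon_mask = meta["kind"] == "exon"
    exon_counts = counts[exon_mask]
    exon_reads = exon_counts.groupby(meta.loc[exon_mask, "gene"]).sum()
    exon_bp = lengths[exon_mask].groupby(meta.loc[exon_mask, "gene"]).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        exon_density = exon_reads.div(exon_bp, axis=0)
    exon_density = exon_density.where(exon_reads > 0)  # zero signal -> NaN

    intron_mask = meta["kind"] == "intron"
    intron_counts = counts[intron_mask]
    intron_density = intron_counts.div(lengths[intron_mask], axis=0)
    dens = exon_density.reindex(meta.loc[intron_mask, "gene"])
    dens.index = intron_counts.index
    ir = intron_density / dens
    ir.index.name = "intron_id"
    return ir


def modulation_coefficient(
    mean_a: np.ndarray, mean_b: np.ndarray, floor: float | None = None,
    scale: str = "log2",
) -> np.ndarray:
    """Cross-condition retention coefficient.

    ``log2`` (default): log2(mean_a / mean_b) after flooring both means at
    the smallest positive IR observed (keeps zero-mean introns finite
    without per-intron tuning).  ``linear``: plain difference of means.
    """
    if scale == "linear":
        return mean_a - mean_b
    if scale != "log2":
        raise ValueError(f"unknown scale {scale!r}")
    if floor is None:
        pooled = np.concatenate([mean_a, mean_b])
        pos = pooled[pooled > 0]
        floor = float(pos.min()) if pos.size else 1e-9
    a = np.maximum(mean_a, floor)
    b = np.maximum(mean_b, floor)
    return np.log2(a / b)


def differential_retention(
    ir_a: pd.DataFrame,
    ir_b: pd.DataFrame,
    fdr: float = 0.05,
    scale: str = "log2",
) -> pd.DataFrame:
    """Per-intron differential retention between two conditions.

    ``ir_a``/``ir_b`` are intron x replicate IR tables (same index).
    Welch t-test across replicates; introns with zero variance in both
    groups or fewer than two finite replicates per group are flagged
    (``tested = False``, p = NaN) and excluded from the BH adjustment.

    Returns columns ``mean_a``, ``mean_b``, ``modulation``, ``p_raw``,
    ``p_adj``, ``tested``, ``bin``.
    """
    if not ir_a.index.equals(ir_b.index):
        ir_b = ir_b.reindex(ir_a.index)
    from .proteomics import _nan_moments

    a = ir_a.to_numpy(dtype=float)
    b = ir_b.to_numpy(dtype=float)
    n_a, mean_a, var_a = _nan_moments(a)
    n_b, mean_b, var_b = _nan_moments(b)
    testable = (n_a >= 2) & (n_b >= 2) & ((var_a > 0) | (var_b > 0))
    testable &= np.isfinite(mean_a) & np.isfinite(mean_b)

    p_raw = np.full(len(ir_a), np.nan)
    if testable.any():
        res = stats.ttest_ind(
            a[testable], b[testable], axis=1, equal_var=False, nan_policy="omit"
        )
        p_raw[testable] = res.pvalue
    p_adj = np.full(len(ir_a), np.nan)
    if testable.any():
        p_adj[testable] = bh_adjust(p_raw[testable])

    mod = modulation_coefficient(mean_a, mean_b, scale=scale)
    mod = np.where(np.isfinite(mean_a) & np.isfinite(mean_b), mod, np.nan)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "modulation": mod,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "tested": testable,
            "significant": testable & (p_adj <= fdr),
        },
        index=ir_a.index,
    )
    out["bin"] = [bin_label(x) for x in out["modulation"]]
    return out


def reversal_analysis(
    er_events: pd.DataFrame,
    kd_events: pd.DataFrame,
    require_significance: bool = True,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-bin fraction of receptor-driven events reverted by the knock-down.

    ``er_events`` must already be filtered to significant receptor-driven
    retention changes (rows = introns, with ``modulation`` and ``bin``);
    ``kd_events`` is the knock-down contrast on the same introns.  An
    event is *reverted* when its knock-down modulation has the opposite
    sign and (by default) is itself significant at ``fdr``.  Empty bins
    report NaN, never 0.
    """
    kd = kd_events.reindex(er_events.index)
    opposite = np.sign(kd["modulation"]) == -np.sign(er_events["modulation"])
    opposite &= kd["modulation"].notna() & er_events["modulation"].notna()
    if require_significance:
        opposite &= kd["significant"].fillna(False).astype(bool)
    rows = []
    for label in BIN_LABELS:
        in_bin = er_events["bin"] == label
        n = int(in_bin.sum())
        n_rev = int((opposite & in_bin).sum())
        frac = n_rev / n if n else np.nan
        rows.append((label, n, n_rev, frac))
    return pd.DataFrame(
        rows, columns=["bin", "n_events", "n_reverted", "fraction_reverted"]
    ).set_index("bin")


def event_filter_vs_control(events_a, events_b) -> pd.Index:
    """A-specific events: set difference on intron ids."""
    return pd.Index(sorted(set(events_a) - set(events_b)))
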
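"""Genomic-interval annotation and binding-site statistics.

Coordinates are 0-based half-open (BED convention) throughout.  Interval
sets are plain DataFrames with columns ``chrom, start, end, name, score,
strand``; the :class:`GenomeWorkspace` declares chromosome lengths and an
optional segment annotation (promoter/TSS/5'UTR/3'UTR/exonic/intronic/
intergenic) used by the segment-enrichment randomization.

The permutation overlap test re-places intervals uniformly within their
chromosomes (lengths and per-chromosome counts preserved) and reports the
plus-one empirical p-value, the poverlap-style procedure; segment
enrichment compares observed bp overlap per segment class against the
mean over uniform randomizations, the GAT-style fold/q-value readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GeneModel
from .enrichment import bh_adjust

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class BedFormatError(ValueError):
    """Malformed BED input (message carries the 1-based line number)."""


@dataclass
class GenomeWorkspace:
    """Chromosome lengths plus an optional segment annotation."""

    lengths: dict
    segments: pd.DataFrame | None = None  # chrom,start,end,label

    def __post_init__(self) -> None:
        if self.segments is not None:
            for _, row in self.segments.iterrows():
                limit = self.lengths.get(row["chrom"])
                if limit is None or row["start"] < 0 or row["end"] > limit:
                    raise ValueError(
                        f"segment {row['chrom']}:{row['start']}-{row['end']} "
                        "outside chromosome bounds"
                    )


def midpoints(intervals: pd.DataFrame) -> pd.Series:
    return (intervals["start"] + intervals["end"]) // 2


def annotate_to_tss(
    peaks: pd.DataFrame,
    models: list[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 100),
) -> pd.DataFrame:
    """Nearest-TSS annotation with a strand-aware promoter window.

    The signed distance is (peak midpoint - TSS), flipped on the minus
    strand so negative always means upstream.  A peak is ``promoter`` when
    the distance falls in ``promoter_window`` (inclusive); otherwise it is
    labeled ``exonic`` / ``intronic`` / ``intergenic`` by the midpoint's
    position in the gene models (exon beats intron beats intergenic).
    """
    lo, hi = promoter_window
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)

    rows = []
    mids = midpoints(peaks)
    for i, peak in peaks.iterrows():
        mid = int(mids.loc[i])
        chrom_models = by_chrom.get(peak["chrom"], [])
        best = None
        for m in chrom_models:
            d = mid - m.tss
            if m.strand == "-":
                d = -d
            if best is None or abs(d) < abs(best[1]):
                best = (m.gene_id, d)
        if best is None:
            rows.append((peak["name"], None, np.nan, "intergenic"))
            continue
        gene_id, dist = best
        if lo <= dist <= hi:
            label = "promoter"
        else:
            label = "intergenic"
            for m in chrom_models:
                if m.start <= mid < m.end:
                    label = "intronic"
                    if any(s <= mid < e for s, e in m.merged_exons):
                        label = "exonic"
                        break
        rows.append((peak["name"], gene_id, dist, label))
    return pd.DataFrame(
        rows, columns=["name", "nearest_gene", "tss_distance", "label"]
    ).set_index("name")


def proximity_pairs(
    set_a: pd.DataFrame, set_b: pd.DataFrame, window: int = 1000
) -> pd.DataFrame:
    """Pairs with midpoints within ``window`` bp (inclusive), same chromosome.

    Each interval of A may pair with several of B.  Returns one row per
    pair with the midpoint distance; callers needing distinct-A counts can
    drop duplicates on ``name_a``.
    """
    mids_a = midpoints(set_a)
    mids_b = midpoints(set_b)
    rows = []
    for chrom in sorted(set(set_a["chrom"]) & set(set_b["chrom"])):
        a = set_a[set_a["chrom"] == chrom]
        b = set_b[set_b["chrom"] == chrom].sort_values("start")
        mb = mids_b.loc[b.index].to_numpy()
        order = np.argsort(mb)
        mb_sorted = mb[order]
        names_b = b["name"].to_numpy()[order]
        for i in a.index:
            ma = int(mids_a.loc[i])
            lo = np.searchsorted(mb_sorted, ma - window, side="left")
            hi = np.searchsorted(mb_sorted, ma + window, side="right")
            for j in range(lo, hi):
                rows.append(
                    (set_a.loc[i, "name"], names_b[j], int(abs(ma - mb_sorted[j])))
                )
    return pd.DataFrame(rows, columns=["name_a", "name_b", "distance"])


def _overlap_count(
    a_start: np.ndarray, a_end: np.ndarray, b_start: np.ndarray, b_end: np.ndarray
) -> int:
    """Number of (a, b) pairs with >=1 bp overlap, single chromosome."""
    order_s = np.argsort(b_start, kind="stable")
    bs = b_start[order_s]
    be_sorted = np.sort(b_end)
    # pairs with b.start < a.end, minus pairs entirely left of a (b.end <= a.start)
    n_start = np.searchsorted(bs, a_end, side="left")
    n_left = np.searchsorted(be_sorted, a_start, side="right")
    return int((n_start - n_left).sum())


def intersect_exact(set_a: pd.DataFrame, set_b: pd.DataFrame) -> pd.DataFrame:
    """All pairs with at least 1 bp overlap (half-open coordinates)."""
    rows = []
    for chrom in sorted(set(set_a["chrom"]) & set(set_b["chrom"])):
        a = set_a[set_a["chrom"] == chrom]
        b = set_b[set_b["chrom"] == chrom]
        bs = b["start"].to_numpy()
        be = b["end"].to_numpy()
        names_b = b["name"].to_numpy()
        for i in a.index:
            s, e = int(a.loc[i, "start"]), int(a.loc[i, "end"])
            hit = (bs < e) & (be > s)
            for nb in names_b[hit]:
                rows.append((a.loc[i, "name"], nb))
    return pd.DataFrame(rows, columns=["name_a", "name_b"])


def count_overlaps(set_a: pd.DataFrame, set_b: pd.DataFrame) -> int:
    """Fast count of >=1 bp overlapping pairs across chromosomes."""
    total = 0
    for chrom in set(set_a["chrom"]) & set(set_b["chrom"]):
        a = set_a[set_a["chrom"] == chrom]
        b = set_b[set_b["chrom"] == chrom]
        total += _overlap_count(
            a["start"].to_numpy(),
            a["end"].to_numpy(),
            b["start"].to_numpy(),
            b["end"].to_numpy(),
        )
    return total


def _random_placement(
    rng: np.random.Generator, lengths: np.ndarray, chrom_len: int
) -> tuple[np.ndarray, np.ndarray]:
    if (lengths > chrom_len).any():
        raise ValueError(
            f"interval longer than its chromosome ({int(lengths.max())} bp "
            f"vs {chrom_len} bp)"
        )
    starts = (rng.random(len(lengths)) * (chrom_len - lengths + 1)).astype(np.int64)
    return starts, starts + lengths


def permutation_overlap_test(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    workspace: GenomeWorkspace,
    n_sims: int = 100_000,
    shuffle_both: bool = True,
    seed: int = 0,
) -> dict:
    """Empirical significance of the overlap between two interval sets.

    Each simulation re-places intervals uniformly within their chromosomes
    (lengths and per-chromosome counts preserved; both sets when
    ``shuffle_both``) and recounts overlapping pairs.  The p-value uses
    the plus-one estimator ``(1 + #{sim >= obs}) / (1 + n_sims)`` and is
    therefore never zero.
    """
    from ._util import rng_for

    rng = rng_for(seed, "overlap_test")
    observed = count_overlaps(set_a, set_b)

    chroms = sorted(set(set_a["chrom"]) | set(set_b["chrom"]))
    per_chrom = []
    for chrom in chroms:
        a = set_a[set_a["chrom"] == chrom]
        b = set_b[set_b["chrom"] == chrom]
        la = (a["end"] - a["start"]).to_numpy()
        lb = (b["end"] - b["start"]).to_numpy()
        per_chrom.append(
            (
                workspace.lengths[chrom],
                la,
                lb,
                a["start"].to_numpy(),
                a["end"].to_numpy(),
            )
        )

    null = np.empty(n_sims, dtype=np.int64)
    for s in range(n_sims):
        total = 0
        for chrom_len, la, lb, a_start, a_end in per_chrom:
            if len(la) == 0 or len(lb) == 0:
                continue
            if shuffle_both:
                sa, ea = _random_placement(rng, la, chrom_len)
            else:
                sa, ea = a_start, a_end
            sb, eb = _random_placement(rng, lb, chrom_len)
            total += _overlap_count(sa, ea, sb, eb)
        null[s] = total
    p = (1 + int((null >= observed).sum())) / (1 + n_sims)
    return {
        "observed": int(observed),
        "null_mean": float(null.mean()),
        "p_value": float(p),
        "n_sims": int(n_sims),
    }


def _segment_bp_overlap(
    peaks: pd.DataFrame | dict, segments: pd.DataFrame, labels: list[str]
) -> dict:
    """Total bp of peak/segment overlap per segment label."""
    out = {lab: 0 for lab in labels}
    for chrom, grp in segments.groupby("chrom"):
        if isinstance(peaks, dict):
            if chrom not in peaks:
                continue
            ps, pe = peaks[chrom]
        else:
            sub = peaks[peaks["chrom"] == chrom]
            ps = sub["start"].to_numpy()
            pe = sub["end"].to_numpy()
        if len(ps) == 0:
            continue
        ss = grp["start"].to_numpy()
        se = grp["end"].to_numpy()
        lab = grp["label"].to_numpy()
        for k in range(len(ss)):
            ov = np.minimum(pe, se[k]) - np.maximum(ps, ss[k])
            ov = ov[ov > 0]
            if ov.size:
                out[lab[k]] += int(ov.sum())
    return out


def segment_enrichment(
    peaks: pd.DataFrame,
    workspace: GenomeWorkspace,
    n_sims: int = 10_000,
    seed: int = 0,
    fold_cut: float = 2.0,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Observed vs expected peak coverage of genome segment classes.

    Observed is the bp overlap of the peaks with each segment class;
    expected is the mean over ``n_sims`` uniform re-placements of the
    peaks within their chromosomes.  Fold = observed/expected (NaN when a
    class is never hit in the null), the empirical p is two-sided with the
    plus-one estimator, q is BH across classes, and ``enriched`` flags
    fold > ``fold_cut`` with q <= ``q_cut``.
    """
    from ._util import rng_for

    if workspace.segments is None:
        raise ValueError("workspace has no segment annotation")
    rng = rng_for(seed, "segment_enrichment")
    labels = sorted(workspace.segments["label"].unique())
    observed = _segment_bp_overlap(peaks, workspace.segments, labels)

    by_chrom = {
        chrom: (grp["end"] - grp["start"]).to_numpy()
        for chrom, grp in peaks.groupby("chrom")
    }
    null = {lab: np.empty(n_sims) for lab in labels}
    for s in range(n_sims):
        placed = {}
        for chrom, lens in by_chrom.items():
            starts, ends = _random_placement(rng, lens, workspace.lengths[chrom])
            placed[chrom] = (starts, ends)
        sim = _segment_bp_overlap(placed, workspace.segments, labels)
        for lab in labels:
            null[lab][s] = sim[lab]

    rows = []
    for lab in labels:
        obs = observed[lab]
        ns = null[lab]
        expected = float(ns.mean())
        fold = obs / expected if expected > 0 else np.nan
        p_hi = (1 + int((ns >= obs).sum())) / (1 + n_sims)
        p_lo = (1 + int((ns <= obs).sum())) / (1 + n_sims)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
        rows.append((lab, obs, expected, fold, p))
    out = pd.DataFrame(
        rows, columns=["label", "observed_bp", "expected_bp", "fold", "p_value"]
    ).set_index("label")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["enriched"] = (out["fold"] > fold_cut) & (out["q_value"] <= q_cut)
    return out


def read_bed(path: str | Path, workspace: GenomeWorkspace | None = None) -> pd.DataFrame:
    """Read BED3-BED6 into the canonical interval DataFrame.

    ``track``/``browser``/``#`` header lines are skipped with a warning;
    coordinate errors name the offending 1-based line.
    """
    import warnings

    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("track", "browser", "#")):
                warnings.warn(f"{path}:{ln}: skipping header line", stacklevel=2)
                continue
            parts = stripped.split("\t")
            if len(parts) < 3:
                raise BedFormatError(f"{path}:{ln}: fewer than 3 BED fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{ln}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}:{ln}: invalid interval [{start}, {end})"
                )
            if workspace is not None:
                limit = workspace.lengths.get(chrom)
                if limit is None:
                    raise BedFormatError(f"{path}:{ln}: unknown chromosome {chrom}")
                if end > limit:
                    raise BedFormatError(
                        f"{path}:{ln}: end {end} beyond {chrom} length {limit}"
                    )
            name = parts[3] if len(parts) > 3 else f"iv_{ln}"
            score = parts[4] if len(parts) > 4 else 0
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical interval DataFrame as BED6."""
    intervals[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
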
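"""Planted-truth simulators for every pipeline input.

Each generator emulates the statistical structure one analysis stage
assumes — negative-binomial IP/input count pairs with an enriched subset in
one cell line, exon/intron count tables whose planted retention shifts
partially revert under a simulated knock-down, interval sets with a
co-localized fraction, and log-normal LFQ matrices with a bait row — and
returns the ground truth alongside the data so downstream recovery is
testable without any external dataset.

All randomness flows from ``SimConfig.seed`` through named sub-streams
(see ``riberflow._util.rng_for``): a fixed seed reproduces every output
byte for byte, and generators never perturb each other's draws.

Counts are negative binomial parameterized by mean ``mu`` and dispersion
``alpha`` (variance ``mu + alpha mu^2``; the NB "size" is ``1/alpha``),
the standard RNA-seq count model.  Per-sample sequencing-depth factors are
drawn log-uniform on ``[1/spread, spread]`` so size-factor estimation is
non-trivial.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import rng_for
from .containers import CountMatrix, GeneModel

#: biotype mix of an ERbeta-associated long-RNA set: mostly protein coding,
#: then antisense lncRNA, pseudogene, processed transcript, lincRNA,
#: sense-intronic and a remainder of small classes.
DEFAULT_BIOTYPE_PROBS = {
    "protein_coding": 0.38,
    "antisense": 0.26,
    "pseudogene": 0.13,
    "processed_transcript": 0.08,
    "lincRNA": 0.07,
    "sense_intronic": 0.04,
    "other": 0.04,
}


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of every synthetic dataset.

    Defaults encode the study design the pipeline targets: triplicate
    IP/input libraries in a case (receptor-expressing) and a control cell
    line, triplicate nascent-RNA libraries in three conditions, and
    triplicate LFQ runs with and without knock-down.
    """

    seed: int = 0
    n_genes: int = 1000
    n_replicates: int = 3
    nb_dispersion: float = 0.02
    baseline_mean: float = 200.0
    enriched_fraction: float = 0.05
    enrichment_log2fc: float = 4.0
    control_enriched_fraction: float = 0.0
    background_ef_sigma: float = 1.5
    library_size_spread: float = 2.0
    ir_shift_log2: float = 1.0
    reversal_fraction: float = 0.78
    reversal_fraction_positive: float | None = 0.55
    coloc_fraction: float = 0.5
    genome_lengths: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_500_000}
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "enriched_fraction",
            "control_enriched_fraction",
            "reversal_fraction",
            "coloc_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("nb_dispersion", "baseline_mean", "library_size_spread"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.background_ef_sigma < 0:
            raise SimConfigError("background_ef_sigma must be >= 0")
        if self.reversal_fraction_positive is not None and not (
            0.0 <= self.reversal_fraction_positive <= 1.0
        ):
            raise SimConfigError("reversal_fraction_positive must be in [0, 1]")
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise SimConfigError("n_replicates must be >= 1")
        if not self.genome_lengths:
            raise SimConfigError("genome_lengths must be nonempty")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimTruth:
    """Ground truth written alongside each simulated dataset."""

    enriched_ids: dict = field(default_factory=dict)  # cell line -> [ids]
    ir_shifted_introns: dict = field(default_factory=dict)  # id -> signed shift
    reverted_introns: list = field(default_factory=list)
    coloc_pairs: list = field(default_factory=list)  # (query_id, ref_id)
    bait_dependent_proteins: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "enriched_ids": {k: sorted(v) for k, v in self.enriched_ids.items()},
            "ir_shifted_introns": dict(sorted(self.ir_shifted_introns.items())),
            "reverted_introns": sorted(self.reverted_introns),
            "coloc_pairs": sorted(map(list, self.coloc_pairs)),
            "bait_dependent_proteins": sorted(self.bait_dependent_proteins),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            enriched_ids={k: set(v) for k, v in raw["enriched_ids"].items()},
            ir_shifted_introns=raw["ir_shifted_introns"],
            reverted_introns=raw["reverted_introns"],
            coloc_pairs=[tuple(p) for p in raw["coloc_pairs"]],
            bait_dependent_proteins=raw["bait_dependent_proteins"],
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mean + dispersion*mean^2."""
    size = 1.0 / dispersion
    mean = np.maximum(mean, 1e-12)
    return rng.negative_binomial(size, size / (size + mean))


def _depth_factors(rng: np.random.Generator, n: int, spread: float) -> np.ndarray:
    lo, hi = np.log(1.0 / spread), np.log(spread)
    return np.exp(rng.uniform(lo, hi, size=n))


def simulate_rip_counts(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """IP/input count pairs for a case and a control cell line.

    Planted enriched features have IP mean = input mean x
    ``2**enrichment_log2fc`` in the case line; the control line gets its
    own (by default empty) planted subset of size
    ``control_enriched_fraction * n_genes``.  Every *unplanted* gene
    additionally carries a nonspecific pull-down efficiency
    ``2**N(0, background_ef_sigma)``, drawn independently per cell line —
    real IP libraries recover every RNA to a variable degree, which is
    what makes the downstream percentile gate meaningful.  Set
    ``background_ef_sigma = 0`` to simulate under the enrichment test's
    exact null.
    """
    cfg.validate()
    rng = rng_for(cfg.seed, "rip")
    genes = [f"gene_{i:05d}" for i in range(cfg.n_genes)]

    # per-gene baseline expression, log-normal around baseline_mean
    base = cfg.baseline_mean * np.exp(rng.normal(0.0, 1.0, cfg.n_genes))

    n_enr = int(round(cfg.enriched_fraction * cfg.n_genes))
    n_ctrl_enr = int(round(cfg.control_enriched_fraction * cfg.n_genes))
    perm = rng.permutation(cfg.n_genes)
    enr_case = perm[:n_enr]
    enr_ctrl = perm[n_enr : n_enr + n_ctrl_enr]

    fc = 2.0 ** cfg.enrichment_log2fc
    ip_mean = {}
    for line, planted in (("case", enr_case), ("control", enr_ctrl)):
        eff = 2.0 ** rng.normal(0.0, cfg.background_ef_sigma, cfg.n_genes)
        eff[enr_case] = 1.0  # planted RNAs: exact effect, no background term
        eff[enr_ctrl] = 1.0
        mu = base * eff
        mu[planted] = base[planted] * fc
        ip_mean[line] = mu

    cols, design_rows, data = [], [], []
    for line in ("case", "control"):
        for fraction in ("input", "IP"):
            mu = base if fraction == "input" else ip_mean[line]
            for rep in range(1, cfg.n_replicates + 1):
                depth = _depth_factors(rng, 1, cfg.library_size_spread)[0]
                data.append(_nb_draw(rng, mu * depth, cfg.nb_dispersion))
                name = f"{line}_{fraction}_r{rep}"
                cols.append(name)
                design_rows.append((name, line, fraction, "steady", rep))

    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="feature_id"), columns=cols
    )
    design = pd.DataFrame(
        design_rows, columns=["sample", "cell_line", "fraction", "condition", "replicate"]
    ).set_index("sample")
    truth = SimTruth(
        enriched_ids={
            "case": {genes[i] for i in enr_case},
            "control": {genes[i] for i in enr_ctrl},
        }
    )
    return CountMatrix(counts, design), truth


def simulate_gene_models(
    cfg: SimConfig,
    n_genes: int | None = None,
    biotype_probs: dict | None = None,
) -> list[GeneModel]:
    """Non-overlapping multi-exon gene models on the configured genome.

    Genes are tiled chromosome by chromosome with random intergenic gaps;
    each has 2-8 exons of 100-500 bp separated by introns of 200-2000 bp,
    a random strand and a biotype drawn from ``biotype_probs``.
    """
    cfg.validate()
    rng = rng_for(cfg.seed, "gene_models")
    n_genes = cfg.n_genes if n_genes is None else n_genes
    probs = biotype_probs or DEFAULT_BIOTYPE_PROBS
    labels = list(probs)
    pvec = np.asarray([probs[k] for k in labels], dtype=float)
    if not np.isclose(pvec.sum(), 1.0):
        raise SimConfigError("biotype probabilities must sum to 1")

    chroms = list(cfg.genome_lengths)
    models: list[GeneModel] = []
    cursor = {c: int(rng.integers(500, 2000)) for c in chroms}
    ci = 0
    for gi in range(n_genes):
        n_ex = int(rng.integers(2, 9))
        ex_lens = rng.integers(100, 501, size=n_ex)
        in_lens = rng.integers(200, 2001, size=n_ex - 1)
        span = int(ex_lens.sum() + in_lens.sum())
        # round-robin over chromosomes, each keeping its own cursor, so
        # genes never overlap; a full genome is a configuration error
        placed = None
        for _ in range(len(chroms)):
            c = chroms[ci]
            if cursor[c] + span <= cfg.genome_lengths[c]:
                placed = c
                break
            ci = (ci + 1) % len(chroms)
        if placed is None:
            raise SimConfigError(
                f"gene {gi} (span {span} bp) does not fit: the genome is too "
                f"small for {n_genes} non-overlapping genes"
            )
        exons = []
        pos = cursor[placed]
        for k in range(n_ex):
            exons.append((pos, pos + int(ex_lens[k])))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = labels[rng.choice(len(labels), p=pvec)]
        models.append(
            GeneModel(
                gene_id=f"gene_{gi:05d}",
                chromosome=placed,
                strand=strand,
                exons=exons,
                biotype=biotype,
            )
        )
        cursor[placed] = pos + int(rng.integers(1000, 5000))
        ci = (ci + 1) % len(chroms)
    return models


NASCENT_CONDITIONS = ("wt", "er", "er_kd")


def simulate_nascent_counts(
    cfg: SimConfig,
    models: list[GeneModel],
    background_ir: float = 0.1,
    coverage_mean: float = 5.0,
) -> tuple[CountMatrix, SimTruth]:
    """Exon/intron nascent-RNA counts in three conditions.

    Conditions are ``wt`` (receptor-negative), ``er`` (receptor-positive)
    and ``er_kd`` (receptor-positive plus simulated knock-down).  Feature
    means are length x per-gene coverage rate; intron means carry a
    baseline retention rate ``background_ir``.  A planted subset of introns
    (``enriched_fraction`` of all introns, signs alternating) has its
    retention multiplied by ``2**(+-ir_shift_log2)`` in ``er`` vs ``wt``; a
    ``reversal_fraction`` of those shifts is undone in ``er_kd`` (retention
    returns to the wt rate), the rest persist.

    Feature ids follow ``gene:exon_k`` / ``gene:intron_k``; a companion
    ``length`` is attached as ``counts.attrs["lengths"]`` and also
    derivable from the models.
    """
    cfg.validate()
    rng = rng_for(cfg.seed, "nascent")

    feat_ids: list[str] = []
    feat_len: list[int] = []
    feat_gene: list[int] = []
    feat_is_intron: list[bool] = []
    intron_ids: list[str] = []
    for gi, model in enumerate(models):
        for k, (s, e) in enumerate(model.merged_exons):
            feat_ids.append(f"{model.gene_id}:exon_{k}")
            feat_len.append(e - s)
            feat_gene.append(gi)
            feat_is_intron.append(False)
        for k, (s, e) in enumerate(model.introns):
            fid = f"{model.gene_id}:intron_{k}"
            feat_ids.append(fid)
            feat_len.append(e - s)
            feat_gene.append(gi)
            feat_is_intron.append(True)
            intron_ids.append(fid)

    lengths = np.asarray(feat_len, dtype=float)
    gene_idx = np.asarray(feat_gene)
    is_intron = np.asarray(feat_is_intron)

    coverage = coverage_mean * np.exp(rng.normal(0.0, 0.5, len(models)))

    n_shift = int(round(cfg.enriched_fraction * len(intron_ids)))
    shuffled = rng.permutation(len(intron_ids))
    shifted_pos = shuffled[:n_shift]
    signs = np.where(np.arange(n_shift) % 2 == 0, 1.0, -1.0)
    shift_map = {
        intron_ids[p]: float(s * cfg.ir_shift_log2)
        for p, s in zip(shifted_pos, signs)
    }
    # reversal planted per shift direction: retention decreases (negative
    # shift) revert at `reversal_fraction`, increases (positive shift) at
    # `reversal_fraction_positive` (same rate when unset)
    rev_pos_frac = (
        cfg.reversal_fraction
        if cfg.reversal_fraction_positive is None
        else cfg.reversal_fraction_positive
    )
    reverted: list[str] = []
    for sign, frac in ((-1.0, cfg.reversal_fraction), (1.0, rev_pos_frac)):
        ids = [
            intron_ids[p]
            for p, s in zip(shifted_pos, signs)
            if s == sign
        ]
        reverted.extend(ids[: int(round(frac * len(ids)))])
    reverted_set = set(reverted)

    row_of = {fid: i for i, fid in enumerate(feat_ids)}
    base_rate = np.where(is_intron, background_ir, 1.0) * coverage[gene_idx]

    rate = {}
    rate["wt"] = base_rate
    er = base_rate.copy()
    for fid, shift in shift_map.items():
        er[row_of[fid]] *= 2.0 ** shift
    rate["er"] = er
    kd = er.copy()
    for fid in reverted_set:
        kd[row_of[fid]] = base_rate[row_of[fid]]
    rate["er_kd"] = kd

    cols, design_rows, data = [], [], []
    for cond in NASCENT_CONDITIONS:
        mu = rate[cond] * lengths
        for rep in range(1, cfg.n_replicates + 1):
            depth = _depth_factors(rng, 1, cfg.library_size_spread)[0]
            data.append(_nb_draw(rng, mu * depth, cfg.nb_dispersion))
            name = f"{cond}_r{rep}"
            cols.append(name)
            design_rows.append((name, "case", "input", cond, rep))

    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(feat_ids, name="feature_id"), columns=cols
    )
    counts.attrs["lengths"] = pd.Series(lengths, index=counts.index, name="length")
    design = pd.DataFrame(
        design_rows, columns=["sample", "cell_line", "fraction", "condition", "replicate"]
    ).set_index("sample")
    truth = SimTruth(ir_shifted_introns=shift_map, reverted_introns=reverted)
    return CountMatrix(counts, design), truth


def simulate_interval_sets(
    cfg: SimConfig,
    n_reference: int = 500,
    n_query: int = 500,
    interval_length: int = 200,
    coloc_distance: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """A reference and a query interval set with a planted co-localized fraction.

    Reference intervals are uniform on the workspace.  ``coloc_fraction``
    of query intervals are centered within ``coloc_distance`` bp of a
    randomly chosen reference midpoint; the remainder are uniform.
    Returns BED-style DataFrames (chrom, start, end, name, score, strand).
    """
    cfg.validate()
    rng = rng_for(cfg.seed, "intervals")
    chroms = list(cfg.genome_lengths)
    lens = np.asarray([cfg.genome_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()

    def _uniform(n, prefix):
        rows = []
        ci = rng.choice(len(chroms), size=n, p=probs)
        for i in range(n):
            c = chroms[ci[i]]
            start = int(rng.integers(0, cfg.genome_lengths[c] - interval_length))
            rows.append((c, start, start + interval_length, f"{prefix}_{i:05d}", 0, "."))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

    ref = _uniform(n_reference, "ref")
    n_coloc = int(round(cfg.coloc_fraction * n_query))
    rows = []
    pairs = []
    targets = rng.integers(0, n_reference, size=n_coloc)
    for i in range(n_coloc):
        r = ref.iloc[int(targets[i])]
        mid = (int(r["start"]) + int(r["end"])) // 2
        offset = int(rng.integers(-coloc_distance, coloc_distance + 1))
        center = mid + offset
        start = center - interval_length // 2
        limit = cfg.genome_lengths[r["chrom"]]
        start = int(np.clip(start, 0, limit - interval_length))
        name = f"query_{i:05d}"
        rows.append((r["chrom"], start, start + interval_length, name, 0, "."))
        pairs.append((name, r["name"]))
    rest = _uniform(n_query - n_coloc, "bg")
    rest["name"] = [f"query_{i:05d}" for i in range(n_coloc, n_query)]
    query = pd.concat(
        [pd.DataFrame(rows, columns=ref.columns), rest], ignore_index=True
    )
    truth = SimTruth(coloc_pairs=pairs)
    return ref, query, truth


def simulate_lfq_matrix(
    cfg: SimConfig,
    n_proteins: int = 300,
    bait_id: str = "ESR2",
    dependent_fraction: float = 0.3,
    reduction_log2fc: float = 1.0,
    noise_sigma: float = 0.1,
    missing_rate: float = 0.05,
) -> tuple[pd.DataFrame, SimTruth]:
    """Log-normal LFQ intensity matrix for control vs knock-down runs.

    Columns are ``NT_r1.. / shKD_r1..`` (``cfg.n_replicates`` each).  The
    bait row is always present in every replicate.  A ``dependent_fraction``
    of non-bait proteins is reduced ``2**reduction_log2fc``-fold in the
    knock-down arm.  Non-bait values go missing (NaN) at ``missing_rate``.

    The bait dominates a pull-down by orders of magnitude and its LFQ value
    is correspondingly precise, so its replicate noise uses a third of
    ``noise_sigma``; any residual bait noise propagates to every
    bait-normalized value as a shared per-column offset downstream.
    """
    cfg.validate()
    if not 0 <= missing_rate < 1:
        raise SimConfigError("missing_rate must be in [0, 1)")
    rng = rng_for(cfg.seed, "lfq")
    prot = [bait_id] + [f"prot_{i:04d}" for i in range(n_proteins - 1)]
    base = 10.0 ** rng.uniform(6, 9, n_proteins)
    base[0] = 5e8  # abundant bait

    n_dep = int(round(dependent_fraction * (n_proteins - 1)))
    dep_idx = 1 + rng.permutation(n_proteins - 1)[:n_dep]
    dep_ids = [prot[i] for i in dep_idx]

    cols = [f"NT_r{r}" for r in range(1, cfg.n_replicates + 1)] + [
        f"shKD_r{r}" for r in range(1, cfg.n_replicates + 1)
    ]
    data = np.empty((n_proteins, len(cols)))
    for j, col in enumerate(cols):
        mu = base.copy()
        if col.startswith("shKD"):
            mu[dep_idx] /= 2.0 ** reduction_log2fc
        # per-replicate handling efficiency soaks the whole column; the
        # bait normalization downstream must absorb it
        eff = np.exp(rng.normal(0.0, 0.3))
        noise = rng.normal(0.0, noise_sigma, n_proteins)
        noise[0] = rng.normal(0.0, noise_sigma / 3.0)  # precise bait
        data[:, j] = mu * eff * np.exp(noise)
    if missing_rate > 0:
        miss = rng.random(data.shape) < missing_rate
        miss[0, :] = False  # bait never missing
        data[miss] = np.nan
    lfq = pd.DataFrame(data, index=pd.Index(prot, name="protein_id"), columns=cols)
    truth = SimTruth(bait_dependent_proteins=dep_ids)
    return lfq, truth


def write_gtf(models: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (1-based closed coordinates, gene_biotype attr)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; gene_biotype "{m.biotype}";'
            fh.write(
                "\t".join(
                    [
                        m.chromosome,
                        "riberflow",
                        "gene",
                        str(m.start + 1),
                        str(m.end),
                        ".",
                        m.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for s, e in m.exons:
                fh.write(
                    "\t".join(
                        [
                            m.chromosome,
                            "riberflow",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            m.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Minimal GTF reader for the dialect written by :func:`write_gtf`.

    Converts 1-based closed coordinates to 0-based half-open.  Only
    ``exon`` records are used to build models; ``gene_id`` and
    ``gene_biotype`` attributes are required.
    """
    import re

    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: malformed GTF record")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            if ftype != "exon":
                continue
            m = re.search(r'gene_id "([^"]+)"', attrs)
            if not m:
                raise ValueError(f"{path}:{ln}: missing gene_id attribute")
            gid = m.group(1)
            bt = re.search(r'gene_biotype "([^"]+)"', attrs)
            biotype = bt.group(1) if bt else "protein_coding"
            exons.setdefault(gid, []).append((int(start) - 1, int(end)))
            meta[gid] = (chrom, strand, biotype)
    models = []
    for gid, exs in exons.items():
        chrom, strand, biotype = meta[gid]
        models.append(
            GeneModel(
                gene_id=gid, chromosome=chrom, strand=strand, exons=exs, biotype=biotype
            )
        )
    return models
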
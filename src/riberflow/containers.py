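"""Core in-memory containers shared across the pipeline stages.

A :class:`CountMatrix` pairs an integer feature x sample count table with a
sample design table (cell line, IP/input fraction, condition, replicate),
mirroring the layout a counting tool such as HTSeq-count produces for a
multi-arm sequencing experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("cell_line", "fraction", "condition", "replicate")
FRACTIONS = ("input", "IP")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class CountMatrix:
    """Integer read counts per feature per sample plus the sample design.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, features as rows, samples as
        columns.
    design
        DataFrame indexed by sample name with columns ``cell_line``,
        ``fraction`` (``input`` or ``IP``), ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValidationError(f"design table missing column(s): {missing}")
        if list(self.counts.columns) != list(self.design.index):
            raise ValidationError(
                "design rows must match count columns in order; "
                f"got samples {list(self.counts.columns)} vs design "
                f"{list(self.design.index)}"
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integral")
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")
        bad = set(self.design["fraction"]) - set(FRACTIONS)
        if bad:
            raise ValidationError(f"unknown fraction label(s): {sorted(bad)}")
        # replicate labels unique within (cell_line, fraction, condition)
        dup = self.design.duplicated(
            subset=["cell_line", "fraction", "condition", "replicate"]
        )
        if dup.any():
            raise ValidationError(
                "replicate labels not unique within (cell_line, fraction, "
                f"condition): {list(self.design.index[dup])}"
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, mask: pd.Series | list[str]) -> "CountMatrix":
        """Return a new matrix restricted to the given samples."""
        if isinstance(mask, pd.Series):
            samples = list(self.design.index[mask])
        else:
            samples = list(mask)
        return CountMatrix(self.counts[samples], self.design.loc[samples])

    def samples_where(self, **levels) -> list[str]:
        """Sample names whose design matches every keyword, e.g.
        ``samples_where(cell_line="case", fraction="IP")``."""
        keep = pd.Series(True, index=self.design.index)
        for col, val in levels.items():
            keep &= self.design[col] == val
        return list(self.design.index[keep])

    def write_tsv(self, counts_path: str | Path, design_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        d = self.design.copy()
        d.insert(0, "sample", d.index)
        d.to_csv(design_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, counts_path: str | Path, design_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t")
        if "feature_id" not in counts.columns:
            raise ValidationError(
                f"{counts_path}: first column must be 'feature_id'"
            )
        counts = counts.set_index("feature_id")
        design = pd.read_csv(design_path, sep="\t")
        if "sample" not in design.columns:
            raise ValidationError(f"{design_path}: missing 'sample' column")
        design = design.set_index("sample")
        return cls(counts, design)


@dataclass
class GeneModel:
    """A gene with exon structure on a declared strand.

    Coordinates are 0-based half-open throughout.  Introns are derived as
    the gaps between merged exons inside the gene span; the TSS is the
    leftmost exon start on ``+`` and the rightmost exon end on ``-``.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "protein_coding"
    _merged: list[tuple[int, int]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene needs >=1 exon")
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"{self.gene_id}: empty exon [{s},{e})")
        self._merged = merge_intervals(self.exons)

    @property
    def merged_exons(self) -> list[tuple[int, int]]:
        return list(self._merged)

    @property
    def start(self) -> int:
        return self._merged[0][0]

    @property
    def end(self) -> int:
        return self._merged[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> list[tuple[int, int]]:
        merged = self._merged
        return [(merged[i][1], merged[i + 1][0]) for i in range(len(merged) - 1)]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended half-open intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]
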
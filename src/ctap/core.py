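"""Shared domain objects: canonical cell types and composition matrices.

The six canonical major cell types are fixed across the whole package; every
composition vector is expressed over them in this order.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical major cell types, fixed order.
CELL_TYPES: tuple[str, ...] = ("T", "B/plasma", "NK", "myeloid", "stromal", "endothelial")

#: Single-letter codes used when naming abundance phenotypes. NK has no letter.
TYPE_LETTERS: dict[str, str] = {
    "endothelial": "E",
    "stromal": "F",
    "myeloid": "M",
    "T": "T",
    "B/plasma": "B",
}

SIMPLEX_ATOL = 1e-9


def round_half_up_percent(fraction: float) -> int:
    """Round ``100 * fraction`` to the nearest integer, halves away from zero.

    Python's builtin ``round`` uses banker's rounding (``round(62.5) == 62``),
    which does not match how percentages are conventionally reported.
    """
    return int(np.floor(100.0 * fraction + 0.5))


def child_seed(seed: int, label: str) -> int:
    """Derive a deterministic per-stage seed from a single run seed."""
    tag = sum((i + 1) * b for i, b in enumerate(label.encode())) % (2**31)
    ss = np.random.SeedSequence([int(seed), tag])
    return int(ss.generate_state(1)[0])


@dataclass
class CompositionMatrix:
    """Samples x cell-type proportion matrix; rows live on the simplex.

    Parameters
    ----------
    proportions
        Array of shape ``(n_samples, n_types)``; each row sums to 1.
    sample_ids
        Sample identifiers, one per row.
    cell_types
        Cell-type names, one per column (defaults to the 6 canonical types).
    counts
        Optional integer cell counts per sample x type (same shape). Needed
        by bootstrap procedures that resample cells within samples.
    """

    proportions: np.ndarray
    sample_ids: list[str]
    cell_types: tuple[str, ...] = CELL_TYPES
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2:
            raise ValueError("proportions must be a 2-D array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.cell_types = tuple(self.cell_types)
        if len(self.cell_types) < 1:
            raise ValueError("at least one cell type is required")
        n, t = self.proportions.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} proportion rows"
            )
        if t != len(self.cell_types):
            raise ValueError(
                f"{len(self.cell_types)} cell types for {t} proportion columns"
            )
        if np.any(self.proportions < 0):
            raise ValueError("proportions must be non-negative")
        row_sums = self.proportions.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-6, rtol=0):
            bad = [self.sample_ids[i] for i in np.where(np.abs(row_sums - 1) > 1e-6)[0]]
            raise ValueError(f"composition rows must sum to 1; violations: {bad}")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != self.proportions.shape:
                raise ValueError("counts shape must match proportions shape")

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        sample_ids: list[str],
        cell_types: tuple[str, ...] = CELL_TYPES,
    ) -> "CompositionMatrix":
        counts = np.asarray(counts)
        totals = counts.sum(axis=1)
        if np.any(totals <= 0):
            bad = [str(sample_ids[i]) for i in np.where(totals <= 0)[0]]
            raise ValueError(f"samples with zero cells: {bad}")
        props = counts / totals[:, None]
        return cls(props, list(sample_ids), tuple(cell_types), counts=counts)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CompositionMatrix":
        return cls(frame.to_numpy(float), list(frame.index.astype(str)),
                   tuple(frame.columns))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(self.cell_types),
        )

    @property
    def n_samples(self) -> int:
        return self.proportions.shape[0]

    def subset(self, sample_ids: list[str]) -> "CompositionMatrix":
        idx = [self.sample_ids.index(str(s)) for s in sample_ids]
        counts = None if self.counts is None else self.counts[idx]
        return CompositionMatrix(
            self.proportions[idx], [self.sample_ids[i] for i in idx],
            self.cell_types, counts=counts,
        )
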
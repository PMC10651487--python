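"""Input-format validation and cohort-manifest consistency checks."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CELL_TYPES

#: Common non-canonical spellings and the canonical type they map to.
TYPE_SYNONYMS: dict[str, str] = {
    "fibroblast": "stromal",
    "fibroblasts": "stromal",
    "mural": "stromal",
    "t cell": "T",
    "t cells": "T",
    "tcell": "T",
    "b": "B/plasma",
    "b cell": "B/plasma",
    "b cells": "B/plasma",
    "plasma": "B/plasma",
    "b/plasma cell": "B/plasma",
    "nk cell": "NK",
    "nk cells": "NK",
    "natural killer": "NK",
    "monocyte": "myeloid",
    "macrophage": "myeloid",
    "myeloid cell": "myeloid",
    "endothelium": "endothelial",
    "endothelial cell": "endothelial",
}


@dataclass
class ValidationReport:
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def add(self, message: str) -> None:
        self.failures.append(message)


@dataclass
class ManifestReport:
    total_cells: int
    total_states: int | None
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def suggest_type(value: str) -> str | None:
    """Suggest a canonical type name for a non-canonical string."""
    low = value.strip().lower()
    for t in CELL_TYPES:
        if low == t.lower():
            return t
    return TYPE_SYNONYMS.get(low)


def check_cell_types(values, report: ValidationReport,
                     context: str = "cell_type") -> None:
    for v in pd.unique(pd.Series(list(values)).astype(str)):
        if v in CELL_TYPES:
            continue
        hint = suggest_type(v)
        msg = f"{context}: non-canonical cell type {v!r}"
        if hint:
            msg += f" (did you mean {hint!r}?)"
        report.add(msg)


def check_mtx(path: Path, report: ValidationReport,
              n_genes: int | None = None, n_cells: int | None = None) -> None:
    try:
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("%%MatrixMarket"):
                report.add(f"{path.name}: missing MatrixMarket header")
                return
            line = fh.readline()
            while line.startswith("%"):
                line = fh.readline()
            rows, cols, _ = (int(x) for x in line.split())
    except Exception as exc:
        report.add(f"{path.name}: unreadable MTX ({exc})")
        return
    if n_genes is not None and rows != n_genes:
        report.add(f"{path.name}: {rows} rows but {n_genes} genes listed")
    if n_cells is not None and cols != n_cells:
        report.add(f"{path.name}: {cols} columns but {n_cells} cells listed")


def check_composition_tsv(path: Path, report: ValidationReport,
                          atol: float = 1e-6) -> None:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        report.add(f"{path.name}: unreadable TSV ({exc})")
        return
    check_cell_types(frame.columns, report, context=f"{path.name} columns")
    vals = frame.to_numpy(dtype=float)
    if np.any(vals < 0):
        report.add(f"{path.name}: negative proportions present")
    sums = vals.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > atol)[0]
    for i in bad:
        report.add(f"{path.name}: row {frame.index[i]!r} sums to "
                   f"{sums[i]:.6g}, violating the simplex constraint")


def check_cells_tsv(path: Path, report: ValidationReport) -> int | None:
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        report.add(f"{path.name}: unreadable TSV ({exc})")
        return None
    required = {"cell_id", "sample_id", "cell_type"}
    missing = required - set(frame.columns)
    if missing:
        report.add(f"{path.name}: missing columns {sorted(missing)}")
        return None
    check_cell_types(frame["cell_type"], report, context=path.name)
    if frame["cell_id"].duplicated().any():
        report.add(f"{path.name}: duplicate cell ids")
    return len(frame)


def validate_inputs(paths: dict[str, str | Path]) -> ValidationReport:
    """Validate a mapping of role -> path.

    Recognized roles: ``mtx``, ``genes``, ``barcodes``, ``cells``,
    ``samples``, ``composition``. Returns a report listing every failure
    (it never raises on content problems).
    """
    report = ValidationReport()
    paths = {k: Path(v) for k, v in paths.items()}
    for role, p in paths.items():
        if not p.exists():
            report.add(f"{role}: file not found: {p}")
    n_genes = n_cells = None
    if "genes" in paths and paths["genes"].exists():
        try:
            n_genes = len(pd.read_csv(paths["genes"], sep="\t"))
        except Exception as exc:
            report.add(f"genes: unreadable ({exc})")
    if "barcodes" in paths and paths["barcodes"].exists():
        try:
            n_cells = len(pd.read_csv(paths["barcodes"], sep="\t"))
        except Exception as exc:
            report.add(f"barcodes: unreadable ({exc})")
    if "mtx" in paths and paths["mtx"].exists():
        check_mtx(paths["mtx"], report, n_genes=n_genes, n_cells=n_cells)
    if "cells" in paths and paths["cells"].exists():
        n_listed = check_cells_tsv(paths["cells"], report)
        if None not in (n_listed, n_cells) and n_listed != n_cells:
            report.add(f"cells: {n_listed} rows but barcodes list "
                       f"{n_cells} cells")
    if "composition" in paths and paths["composition"].exists():
        check_composition_tsv(paths["composition"], report)
    if "samples" in paths and paths["samples"].exists():
        try:
            frame = pd.read_csv(paths["samples"], sep="\t")
            if "sample_id" not in frame.columns:
                report.add("samples: missing sample_id column")
        except Exception as exc:
            report.add(f"samples: unreadable ({exc})")
    return report


def validate_manifest(cells_per_lineage: dict[str, int],
                      states_per_lineage: dict[str, int] | None = None,
                      ) -> ManifestReport:
    """Consistency-check a cohort manifest of per-lineage cell/state counts.

    Verifies that the lineages are exactly the six canonical types and that
    counts are non-negative integers, and reports the total cell count and
    (when given) the total number of fine states.
    """
    failures: list[str] = []
    if set(cells_per_lineage) != set(CELL_TYPES):
        failures.append(
            f"lineages must be exactly {sorted(CELL_TYPES)}; got "
            f"{sorted(cells_per_lineage)}")
    for t, c in cells_per_lineage.items():
        if int(c) != c or c < 0:
            failures.append(f"cell count for {t!r} must be a non-negative "
                            f"integer")
    total_cells = int(sum(int(c) for c in cells_per_lineage.values()))
    total_states = None
    if states_per_lineage is not None:
        if set(states_per_lineage) != set(CELL_TYPES):
            failures.append(
                f"state-count lineages must be exactly {sorted(CELL_TYPES)}; "
                f"got {sorted(states_per_lineage)}")
        for t, c in states_per_lineage.items():
            if int(c) != c or c < 0:
                failures.append(f"state count for {t!r} must be a "
                                f"non-negative integer")
        total_states = int(sum(int(c) for c in states_per_lineage.values()))
    return ManifestReport(total_cells, total_states, failures)
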
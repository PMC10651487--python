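"""Plain-text on-disk layout for synthetic cohorts.

A cohort directory contains::

    matrix.mtx              MatrixMarket coordinate integer, genes x cells
    genes.tsv               one gene id per line (header: gene_id)
    barcodes.tsv            one cell id per line (header: cell_id)
    cells.tsv               cell_id, sample_id, cell_type, state, emb_1..emb_d
    samples.tsv             per-sample covariates, indexed by sample_id
    truth_phenotype.tsv     per-sample generating phenotype label
    truth_composition.tsv   per-sample true composition over the 6 types

``read_cohort(write_cohort(x)) == x`` on all serialized fields.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .core import CELL_TYPES
from .simulate import SyntheticCohort, Truth


class CohortIOError(ValueError):
    """Raised when a cohort directory is malformed."""


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Serialize a cohort to ``directory`` (created if needed)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    counts = sparse.coo_matrix(cohort.counts).astype(np.int64)
    scio.mmwrite(d / "matrix.mtx", counts, field="integer")
    pd.Series(cohort.gene_ids, name="gene_id").to_csv(
        d / "genes.tsv", sep="\t", index=False)
    pd.Series(cohort.cells["cell_id"].tolist(), name="cell_id").to_csv(
        d / "barcodes.tsv", sep="\t", index=False)
    cohort.cells.to_csv(d / "cells.tsv", sep="\t", index=False)
    cohort.sample_meta.to_csv(d / "samples.tsv", sep="\t")
    cohort.truth.phenotype.rename("phenotype").to_csv(
        d / "truth_phenotype.tsv", sep="\t")
    cohort.truth.composition.to_csv(d / "truth_composition.tsv", sep="\t")
    return d


def _read_single_column(path: Path, column: str) -> list[str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns) != [column]:
        raise CohortIOError(f"{path.name}: expected single column {column!r}, "
                            f"found {list(frame.columns)}")
    return frame[column].tolist()


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Load a cohort directory, validating dimensions along the way."""
    d = Path(directory)
    for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv", "cells.tsv",
                 "samples.tsv", "truth_phenotype.tsv",
                 "truth_composition.tsv"):
        if not (d / name).exists():
            raise CohortIOError(f"missing cohort file: {name}")
    try:
        counts = sparse.csr_matrix(scio.mmread(d / "matrix.mtx")).astype(
            np.int64)
    except Exception as exc:
        raise CohortIOError(f"malformed MatrixMarket file matrix.mtx: {exc}"
                            ) from exc
    gene_ids = _read_single_column(d / "genes.tsv", "gene_id")
    barcodes = _read_single_column(d / "barcodes.tsv", "cell_id")
    if counts.shape[0] != len(gene_ids):
        raise CohortIOError(
            f"dimension mismatch: matrix has {counts.shape[0]} rows but "
            f"genes.tsv lists {len(gene_ids)} genes")
    if counts.shape[1] != len(barcodes):
        raise CohortIOError(
            f"dimension mismatch: matrix has {counts.shape[1]} columns but "
            f"barcodes.tsv lists {len(barcodes)} cells")
    cells = pd.read_csv(d / "cells.tsv", sep="\t",
                    float_precision="round_trip")
    if cells["cell_id"].tolist() != barcodes:
        raise CohortIOError("cells.tsv cell ids do not match barcodes.tsv")
    sample_meta = pd.read_csv(d / "samples.tsv", sep="\t",
                              index_col="sample_id",
                              float_precision="round_trip")
    missing = set(cells["sample_id"]) - set(sample_meta.index)
    if missing:
        raise CohortIOError(f"cells reference unknown samples: "
                            f"{sorted(map(str, missing))}")
    phen = pd.read_csv(d / "truth_phenotype.tsv", sep="\t",
                       index_col="sample_id")["phenotype"]
    comp = pd.read_csv(d / "truth_composition.tsv", sep="\t",
                       index_col="sample_id",
                       float_precision="round_trip")
    if list(comp.columns) != list(CELL_TYPES):
        raise CohortIOError(f"truth_composition.tsv columns must be "
                            f"{list(CELL_TYPES)}")
    truth = Truth(phenotype=phen, composition=comp,
                  state=cells["state"].copy())
    return SyntheticCohort(cells, counts, gene_ids, sample_meta, truth)
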
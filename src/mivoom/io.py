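"""Plain-text fixture formats: counts (TSV + MatrixMarket), metadata, truth.

Layout of a fixture directory:

    counts.tsv        genes x samples, header row of sample ids, first column gene_id
    counts.mtx        MatrixMarket coordinate, 1-based indices
    genes.txt         row names for counts.mtx, one per line
    samples.txt       column names for counts.mtx, one per line
    metadata.csv      one row per sample; empty string encodes a missing cell
    annotation.tsv    gene_id TAB biotype
    truth.json        simulation truth (optional)
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .cohort import CohortTable, CovariateSchema
from .counts import CountMatrix, SimulationTruth

__all__ = ["write_fixture", "read_fixture", "read_counts_tsv", "read_counts_mtx",
           "read_metadata", "read_annotation", "FixtureFormatError"]


class FixtureFormatError(ValueError):
    """Malformed fixture file, with file and (where known) line diagnostics."""


def write_fixture(
    cohort: CohortTable,
    counts: CountMatrix,
    truth: SimulationTruth | None,
    directory: str | os.PathLike,
) -> None:
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)

    frame = counts.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(os.path.join(directory, "counts.tsv"), sep="\t")

    coo = sparse.coo_matrix(counts.counts)
    scipy_io.mmwrite(os.path.join(directory, "counts.mtx"), coo)
    with open(os.path.join(directory, "genes.txt"), "w") as fh:
        fh.write("\n".join(map(str, counts.gene_ids)) + "\n")
    with open(os.path.join(directory, "samples.txt"), "w") as fh:
        fh.write("\n".join(map(str, counts.sample_ids)) + "\n")

    cohort.data.to_csv(os.path.join(directory, "metadata.csv"), na_rep="")

    if counts.biotype is not None:
        ann = counts.biotype.rename("biotype").to_frame()
        ann.index.name = "gene_id"
        ann.to_csv(os.path.join(directory, "annotation.tsv"), sep="\t")

    if truth is not None:
        with open(os.path.join(directory, "truth.json"), "w") as fh:
            fh.write(truth.to_json())


def read_counts_tsv(path: str | os.PathLike, annotation: pd.Series | None = None) -> CountMatrix:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FixtureFormatError(f"{path}: {exc}") from exc
    if frame.empty and frame.columns.empty:
        raise FixtureFormatError(f"{path}: no samples found")
    arr = frame.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = frame.columns[[not np.issubdtype(d, np.number) for d in frame.dtypes]]
        raise FixtureFormatError(f"{path}: non-numeric count columns {list(bad)}")
    if np.isnan(arr.astype(float)).any():
        row = int(np.argwhere(np.isnan(arr.astype(float)))[0][0])
        raise FixtureFormatError(f"{path}: missing count value at data line {row + 2}")
    return CountMatrix(
        counts=arr.astype(np.int64),
        gene_ids=frame.index,
        sample_ids=frame.columns,
        biotype=annotation,
    )


def read_counts_mtx(
    mtx_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    samples_path: str | os.PathLike,
    annotation: pd.Series | None = None,
) -> CountMatrix:
    try:
        mat = scipy_io.mmread(os.fspath(mtx_path))
    except ValueError as exc:
        raise FixtureFormatError(f"{mtx_path}: {exc}") from exc
    with open(genes_path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    with open(samples_path) as fh:
        samples = [line.strip() for line in fh if line.strip()]
    dense = np.asarray(sparse.coo_matrix(mat).todense())
    if dense.shape != (len(genes), len(samples)):
        raise FixtureFormatError(
            f"{mtx_path}: matrix shape {dense.shape} does not match "
            f"{len(genes)} genes x {len(samples)} samples"
        )
    return CountMatrix(
        counts=dense.astype(np.int64),
        gene_ids=pd.Index(genes, name="gene_id"),
        sample_ids=pd.Index(samples),
        biotype=annotation,
    )


def read_metadata(path: str | os.PathLike, schema: CovariateSchema | None = None) -> CohortTable:
    schema = schema or CovariateSchema()
    try:
        df = pd.read_csv(path, index_col=0, na_values=[""], keep_default_na=True)
    except pd.errors.ParserError as exc:
        raise FixtureFormatError(f"{path}: {exc}") from exc
    numeric = set(schema.continuous) | set(schema.binary) | set(schema.exposures) | set(schema.cte_items)
    for col in df.columns:
        if col in numeric:
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError) as exc:
                raise FixtureFormatError(f"{path}: column {col!r} not numeric: {exc}") from exc
    return CohortTable(df, schema)


def read_annotation(path: str | os.PathLike) -> pd.Series:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise FixtureFormatError(f"{path}: {exc}") from exc
    if not {"gene_id", "biotype"} <= set(df.columns):
        raise FixtureFormatError(f"{path}: expected columns gene_id, biotype")
    return df.set_index("gene_id")["biotype"]


def read_fixture(directory: str | os.PathLike):
    """Read a fixture directory back into (cohort, counts, truth | None).

    Counts are read from counts.tsv; annotation from annotation.tsv when
    present.
    """
    directory = os.fspath(directory)
    ann_path = os.path.join(directory, "annotation.tsv")
    annotation = read_annotation(ann_path) if os.path.exists(ann_path) else None
    counts = read_counts_tsv(os.path.join(directory, "counts.tsv"), annotation)
    cohort = read_metadata(os.path.join(directory, "metadata.csv"))
    truth = None
    truth_path = os.path.join(directory, "truth.json")
    if os.path.exists(truth_path):
        with open(truth_path) as fh:
            truth = SimulationTruth.from_json(fh.read())
    return cohort, counts, truth
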
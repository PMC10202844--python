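"""TSV readers and writers for counts, sample metadata, edge lists and results.

All files are tab-separated UTF-8; lines starting with ``#`` are comments.
Result writers prepend a comment block recording the configuration snapshot
and seed so every output is self-describing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ConsistencyError,
    FormatError,
    PipelineConfig,
    StudyDesign,
    TranscriptCountMatrix,
)

logger = logging.getLogger("mnrseq")

_READ_KW = dict(sep="\t", comment="#", dtype_backend="numpy_nullable")


def read_counts(path: str | Path) -> TranscriptCountMatrix:
    """Read a transcript count TSV (transcript_id, gene_symbol, <samples...>)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty counts file: {path}") from exc
    required = ["transcript_id", "gene_symbol"]
    if list(df.columns[:2]) != required:
        raise FormatError(
            f"counts file must start with columns {required}, got {list(df.columns[:2])}"
        )
    if df.shape[0] == 0 or df.shape[1] <= 2:
        raise FormatError("counts file has no data rows or no sample columns")
    sample_ids = [str(c) for c in df.columns[2:]]
    body = df.iloc[:, 2:]
    arr = body.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError("non-numeric count entries")
    if np.isnan(arr.astype(float)).any():
        raise FormatError("missing count entries")
    if np.any(arr.astype(float) != np.floor(arr.astype(float))):
        raise FormatError("counts must be integers")
    if (arr.astype(float) < 0).any():
        raise FormatError("counts must be nonnegative")
    matrix = TranscriptCountMatrix(
        transcript_ids=df["transcript_id"].astype(str).tolist(),
        gene_symbols=df["gene_symbol"].astype(str).tolist(),
        sample_ids=sample_ids,
        counts=arr.astype(np.int64),
    )
    logger.info(
        "read_counts: %d transcripts x %d samples from %s",
        matrix.n_transcripts,
        matrix.n_samples,
        path,
    )
    return matrix


def write_counts(matrix: TranscriptCountMatrix, path: str | Path,
                 header_comments: list[str] | None = None) -> None:
    df = pd.DataFrame(matrix.counts, columns=matrix.sample_ids)
    df.insert(0, "gene_symbol", matrix.gene_symbols)
    df.insert(0, "transcript_id", matrix.transcript_ids)
    _write_tsv(df, path, header_comments)


def read_design(path: str | Path, matrix: TranscriptCountMatrix | None = None) -> StudyDesign:
    """Read sample metadata (sample_id, group, sex, gestational_day).

    When ``matrix`` is given, the design must cover exactly the matrix's
    samples and is reordered to the matrix column order.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty design file: {path}") from exc
    needed = {"sample_id", "group", "sex", "gestational_day"}
    if not needed.issubset(df.columns):
        raise FormatError(f"design file must have columns {sorted(needed)}")
    try:
        days = df["gestational_day"].astype(int).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError("gestational_day must be integer") from exc
    ids = df["sample_id"].astype(str).tolist()
    if matrix is not None:
        # sample coverage is checked before the model matrix is built so a
        # mismatch surfaces as a consistency error, not a rank problem
        if set(ids) != set(matrix.sample_ids) or len(ids) != len(matrix.sample_ids):
            missing = sorted(set(matrix.sample_ids) - set(ids))[:5]
            extra = sorted(set(ids) - set(matrix.sample_ids))[:5]
            raise ConsistencyError(
                f"sample mismatch between design and count matrix: "
                f"missing {missing}, unexpected {extra}"
            )
        order = {s: i for i, s in enumerate(matrix.sample_ids)}
        df = df.iloc[np.argsort([order[s] for s in ids])]
        ids = df["sample_id"].astype(str).tolist()
        days = df["gestational_day"].astype(int).to_numpy()
    design = StudyDesign(
        sample_ids=ids,
        group=df["group"].astype(str).to_numpy(dtype=object),
        sex=df["sex"].astype(str).to_numpy(dtype=object),
        gestational_day=days,
    )
    logger.info("read_design: %d samples, timepoints %s", design.n_samples, design.timepoints)
    return design


def write_design(design: StudyDesign, path: str | Path,
                 header_comments: list[str] | None = None) -> None:
    df = pd.DataFrame(
        {
            "sample_id": design.sample_ids,
            "group": design.group,
            "sex": design.sex,
            "gestational_day": design.gestational_day,
        }
    )
    _write_tsv(df, path, header_comments)


def read_edges(path: str | Path, min_score: float | None = None) -> nx.Graph:
    """Read a gene-interaction edge list (gene_a, gene_b[, score]).

    Self-loops are dropped and duplicate edges collapsed; the graph is
    simple and undirected.  ``min_score`` filters edges below a confidence
    score when a score column is present; scores are otherwise ignored for
    topology.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty edge file: {path}") from exc
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise FormatError("edge file must have columns gene_a, gene_b[, score]")
    if min_score is not None and "score" in df.columns:
        df = df[df["score"].astype(float) >= min_score]
    g = nx.Graph()
    for a, b in zip(df["gene_a"].astype(str), df["gene_b"].astype(str)):
        if a == b:
            continue
        g.add_edge(a, b)
    logger.info("read_edges: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return g


def write_edges(g: nx.Graph, path: str | Path) -> None:
    rows = sorted((min(a, b), max(a, b)) for a, b in g.edges())
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b"])
    _write_tsv(df, path, None)


def config_header(config: PipelineConfig, seed: int | None = None) -> list[str]:
    """Comment lines describing the configuration used to produce a result."""
    lines = [f"config.{k}: {v}" for k, v in config.snapshot().items()]
    if seed is not None:
        lines.append(f"seed: {seed}")
    lines.append("time encoding: t = (gestational_day - midrange)/halfrange; "
                 "reference levels: group=CON, sex=F")
    return lines


def _write_tsv(df: pd.DataFrame, path: str | Path,
               header_comments: list[str] | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_result_table(df: pd.DataFrame, path: str | Path,
                       config: PipelineConfig | None = None,
                       seed: int | None = None) -> None:
    comments = config_header(config, seed) if config is not None else None
    _write_tsv(df, path, comments)
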
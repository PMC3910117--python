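"""Reading and writing expression matrices, labels, and parameter tables.

The expression format is plain TSV: one header line of time-point labels,
then one row per gene with the gene identifier in the first column and m
numeric values.  Genes with any missing or unparseable value are excluded
at load time (whole-row exclusion, no imputation) and recorded with a
reason, mirroring standard preprocessing of public cell-cycle matrices.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ModelParams, Profile

__all__ = [
    "ExpressionDataset",
    "MalformedFileError",
    "EmptyDatasetError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "write_cluster_params_tsv",
    "write_params_json",
]


class MalformedFileError(ValueError):
    """Structurally invalid expression file (ragged rows, duplicate ids...)."""


class EmptyDatasetError(ValueError):
    """No usable gene rows remain after exclusions."""


@dataclasses.dataclass(frozen=True)
class ExpressionDataset:
    """An N x m expression matrix with gene identifiers and exclusion log."""

    gene_ids: list[str]
    matrix: np.ndarray
    delta: float
    excluded_genes: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    def to_profiles(self) -> list[Profile]:
        return [
            Profile(gene_id=g, values=row, delta=self.delta)
            for g, row in zip(self.gene_ids, self.matrix)
        ]


def _parse_cell(raw: str) -> float:
    raw = raw.strip()
    if raw == "" or raw.upper() in {"NA", "NAN", "NULL"}:
        return float("nan")
    return float(raw)


def read_expression_tsv(path: str | Path, delta: float = 1.0) -> ExpressionDataset:
    """Load an expression TSV, excluding genes with missing values.

    Rows whose cell count disagrees with the header raise
    :class:`MalformedFileError`; rows with empty or unparseable cells are
    excluded (with a recorded reason) rather than imputed; duplicate gene
    identifiers are rejected.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise EmptyDatasetError(f"{path} holds no gene rows")
    header = lines[0].split("\t")
    m = len(header) - 1
    if m < 1:
        raise MalformedFileError(f"{path}: header has no time-point columns")

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    excluded: list[tuple[str, str]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        gene_id = cells[0].strip()
        if len(cells) != m + 1:
            raise MalformedFileError(
                f"{path}:{lineno}: expected {m + 1} columns, found {len(cells)}"
            )
        if gene_id in seen:
            raise MalformedFileError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        try:
            values = np.array([_parse_cell(c) for c in cells[1:]])
        except ValueError:
            excluded.append((gene_id, "unparseable value"))
            continue
        if not np.all(np.isfinite(values)):
            excluded.append((gene_id, "missing value"))
            continue
        gene_ids.append(gene_id)
        rows.append(values)
    if not rows:
        raise EmptyDatasetError(f"{path}: no genes left after exclusions")
    return ExpressionDataset(
        gene_ids=gene_ids,
        matrix=np.vstack(rows),
        delta=delta,
        excluded_genes=excluded,
    )


def write_expression_tsv(dataset: ExpressionDataset | Sequence[Profile], path: str | Path) -> None:
    """Write profiles as an expression TSV (header t1..tm).

    Values are written with shortest round-trip precision so that reading
    the file back reproduces the matrix bit for bit.
    """
    if isinstance(dataset, ExpressionDataset):
        gene_ids, matrix = dataset.gene_ids, dataset.matrix
    else:
        profiles = list(dataset)
        gene_ids = [p.gene_id for p in profiles]
        matrix = np.vstack([p.values for p in profiles])
    m = matrix.shape[1]
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(f"t{i}" for i in range(1, m + 1)) + "\n")
        for gene_id, row in zip(gene_ids, matrix):
            fh.write(gene_id + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_labels_tsv(
    gene_ids: Sequence[str], labels: Sequence[int], path: str | Path
) -> None:
    pd.DataFrame({"gene_id": list(gene_ids), "label": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if not {"gene_id", "label"} <= set(frame.columns):
        raise MalformedFileError(f"{path}: need columns gene_id and label")
    return frame


def write_cluster_params_tsv(
    cluster_params: Sequence[ModelParams | None],
    sizes: Sequence[int],
    path: str | Path,
) -> None:
    """Per-cluster parameter table (alpha, omega, a, b, c, d, size)."""
    rows = []
    for k, (params, size) in enumerate(zip(cluster_params, sizes)):
        row: dict[str, object] = {"cluster": k, "size": int(size)}
        for name in ("alpha", "omega", "a", "b", "c", "d"):
            row[name] = getattr(params, name) if params is not None else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_params_json(
    params_by_gene: dict[str, ModelParams | None], path: str | Path
) -> None:
    """True or fitted parameters as JSON, keyed by gene id."""
    payload = {
        gene: (None if p is None else dataclasses.asdict(p))
        for gene, p in params_by_gene.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
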
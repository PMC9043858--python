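"""Readers and writers for count matrices, labels, expression and models.

Dialects:

* dense CSV/TSV counts: header row = gene names, first column = cell
  barcodes, one row per cell;
* sparse MatrixMarket directory (10x convention): ``matrix.mtx`` stored
  gene-major (genes x cells, 1-based coordinates) with sidecar
  ``genes.tsv`` and ``barcodes.tsv``; transposed to cells x genes on
  load;
* labels/predictions: two-column TSV (cell_id, label), optional header;
* models: a versioned JSON container with weights, intercepts, scaler,
  config, class map and gene list.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .celltyper import ClassMap
from .matrix import CountMatrix, ExpressionMatrix
from .rmtl import RMTLConfig, RMTLModel

MODEL_SCHEMA_VERSION = 1


def derive_seed(master_seed: int, *keys: int) -> int:
    """Stable sub-seed derivation from a master seed (always < 2**31)."""
    return int(np.random.SeedSequence([int(master_seed), *map(int, keys)]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# count matrices


def _infer_format(path: str | Path) -> str:
    p = Path(path)
    if p.is_dir():
        return "mtx_dir"
    if p.suffix.lower() == ".csv":
        return "csv"
    if p.suffix.lower() in (".tsv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot infer count format from {p.name!r}; pass format explicitly")


def _read_dense(path: Path, sep: str) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):  # pandas would silently rename these
        raise ValueError(f"{path}: duplicate gene names in header")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty count table")
    return CountMatrix(df.to_numpy(), [str(c) for c in df.index], [str(g) for g in df.columns])


def _read_mtx_dir(path: Path) -> CountMatrix:
    mtx = path / "matrix.mtx"
    genes_f = path / "genes.tsv"
    barcodes_f = path / "barcodes.tsv"
    for f in (mtx, genes_f, barcodes_f):
        if not f.exists():
            raise FileNotFoundError(f"MTX directory {path} is missing {f.name}")
    mat = scipy.io.mmread(mtx)  # gene-major: genes x cells
    genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_f, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape[0] != len(genes):
        raise ValueError(
            f"MTX header says {mat.shape[0]} genes but genes.tsv lists {len(genes)}"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"MTX header says {mat.shape[1]} cells but barcodes.tsv lists {len(barcodes)}"
        )
    dense = np.asarray(mat.todense()).T if sp.issparse(mat) else np.asarray(mat).T
    return CountMatrix(dense, barcodes, genes)


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Load a count matrix from dense CSV/TSV or a 10x-style MTX directory."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_dense(path, ",")
    if fmt == "tsv":
        return _read_dense(path, "\t")
    if fmt == "mtx_dir":
        return _read_mtx_dir(path)
    raise ValueError(f"unknown count format {fmt!r}; choose csv, tsv or mtx_dir")


def write_counts(counts: CountMatrix, path: str | Path, format: str | None = None) -> None:
    """Write counts as dense CSV/TSV or a gene-major MTX directory."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(counts.values, index=counts.cell_ids, columns=counts.gene_ids).to_csv(
            path, sep=sep
        )
        return
    if fmt == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(counts.values.T))
        pd.Series(counts.gene_ids).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(counts.cell_ids).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
        return
    raise ValueError(f"unknown count format {fmt!r}")


# ---------------------------------------------------------------------------
# expression matrices


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_ids).to_csv(path, sep="\t")


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float), [str(c) for c in df.index], [str(g) for g in df.columns]
    )


# ---------------------------------------------------------------------------
# labels


def read_labels(path: str | Path, cell_ids: list[str] | None = None) -> dict[str, str]:
    """Two-column TSV (cell_id, label) -> mapping; header auto-detected.

    A first line whose first field matches none of the known cell ids
    (when given) or equals 'cell_id'/'cell' is treated as a header.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty label file")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns (cell_id, label)")
    first = str(df.iloc[0, 0])
    is_header = first.lower() in ("cell_id", "cell", "barcode")
    if cell_ids is not None and not is_header:
        is_header = first not in set(cell_ids) and all(
            str(x) in set(cell_ids) for x in df.iloc[1:, 0]
        )
    if is_header:
        df = df.iloc[1:]
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dups = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"{path}: duplicate cell ids {dups[:5]}")
    return dict(zip(ids, df.iloc[:, 1].astype(str).tolist()))


def align_labels(mapping: dict[str, str], cell_ids: list[str]) -> list[str]:
    """Reorder a label mapping to the matrix cell order.

    Label-file ids absent from the matrix are warned about and dropped;
    matrix cells without a label raise.
    """
    known = set(cell_ids)
    unknown = [c for c in mapping if c not in known]
    if len(mapping) > 0 and len(unknown) == len(mapping):
        raise ValueError("no overlap between label file cell ids and matrix cell ids")
    if unknown:
        warnings.warn(
            f"{len(unknown)} label-file cell ids not in the matrix "
            f"(e.g. {unknown[:3]}); excluded",
            stacklevel=2,
        )
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"{len(missing)} matrix cells have no label (e.g. {missing[:3]})")
    return [mapping[c] for c in cell_ids]


def write_labels(cell_ids: list[str], labels: list[str], path: str | Path,
                 header: tuple[str, str] = ("cell_id", "label")) -> None:
    pd.DataFrame({header[0]: cell_ids, header[1]: labels}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# models


def save_model(
    model: RMTLModel, class_map: ClassMap, gene_ids: list[str], path: str | Path
) -> None:
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "W0": model.W0.tolist(),
        "V": model.V.tolist(),
        "intercepts": model.intercepts.tolist(),
        "scaler": None
        if model.scaler is None
        else {"mean": model.scaler[0].tolist(), "scale": model.scaler[1].tolist()},
        "config": dataclasses.asdict(model.config),
        "classes": class_map.classes,
        "gene_ids": list(gene_ids),
        "objective_trace": [float(v) for v in model.objective_trace],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_model(path: str | Path) -> tuple[RMTLModel, ClassMap, list[str]]:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r}")
    scaler = payload["scaler"]
    model = RMTLModel(
        W0=np.asarray(payload["W0"], dtype=float),
        V=np.asarray(payload["V"], dtype=float),
        intercepts=np.asarray(payload["intercepts"], dtype=float),
        config=RMTLConfig(**payload["config"]),
        scaler=None
        if scaler is None
        else (np.asarray(scaler["mean"], dtype=float), np.asarray(scaler["scale"], dtype=float)),
        objective_trace=np.asarray(payload["objective_trace"], dtype=float),
        task_names=list(payload["classes"]),
    )
    return model, ClassMap(list(payload["classes"])), list(payload["gene_ids"])
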
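"""Readers, writers and run configuration.

Formats are plain text throughout: expression as TSV (genes in rows) or
Matrix Market with ``.rows``/``.cols`` sidecar name files, gene sets as
GMT, clinical and mutation tables as TSV, gene lists one per line,
configuration and ground truth as YAML.  Gene identifiers are opaque,
case-sensitive strings.  Numeric artifacts are written at full precision
so that writer/reader pairs round-trip bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression(path, transpose: bool = False) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV or Matrix Market.

    TSV expects a header row of sample ids and gene ids in the first
    column.  An ``.mtx`` file expects sidecar ``<stem>.rows`` and
    ``<stem>.cols`` files with one identifier per line.  Duplicate gene
    ids, NaN and negative values are rejected.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = path.with_suffix(".rows").read_text().splitlines()
        cols = path.with_suffix(".cols").read_text().splitlines()
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=rows, columns=cols)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
    if transpose:
        df = df.T
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id in expression matrix: {dup[0]!r}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError("non-numeric values in expression matrix (ragged rows?)")
    if np.isnan(vals).any():
        raise ValueError("NaN values in expression matrix")
    if (vals < 0).any():
        raise ValueError("negative values in expression matrix")
    df.index.name = "gene"
    return df


def write_expression(expr: pd.DataFrame, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        expr.to_csv(path, sep="\t", float_format="%.17g")
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(expr.to_numpy()))
        path.with_suffix(".rows").write_text("\n".join(map(str, expr.index)) + "\n")
        path.with_suffix(".cols").write_text("\n".join(map(str, expr.columns)) + "\n")
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


# ---------------------------------------------------------------------------
# Gene sets, gene lists, tables
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets (name, description, members); duplicates within
    a set are collapsed, empty lines skipped with a warning."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            logger.warning("GMT %s: empty line %d skipped", path, lineno)
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {lineno}: expected name, description, members")
        name, members = parts[0], [g for g in parts[2:] if g]
        deduped = list(dict.fromkeys(members))
        if not deduped:
            raise ValueError(f"GMT line {lineno}: set {name!r} is empty")
        sets[name] = deduped
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(members) for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> list[str]:
    return [g for g in Path(path).read_text().splitlines() if g.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if len(genes) else ""))


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event flag must be 0/1")
    if "response" in df.columns:
        bad = set(df["response"].dropna()) - {"CR", "PR", "SD", "PD", "NA"}
        if bad:
            raise ValueError(f"unknown response labels: {sorted(bad)}")
    return df


def read_mutations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample", "gene", "variant_classification"} - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.17g")


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Paths and parameters of a full pipeline run."""

    # inputs (None = stage skipped or simulated upstream)
    expression: str | None = None  # single-cell genes x cells
    lineages: str | None = None  # TSV: cell, lineage
    regulons: str | None = None  # pre-inferred edge table; else inferred
    tf_list: str | None = None  # one TF per line, for inference
    immune_list: str | None = None
    bulk_expression: str | None = None
    clinical: str | None = None
    mutations: str | None = None
    gene_sets: str | None = None  # GMT, optional extra scoring

    # parameters
    auc_threshold: float = 0.05
    top_fraction: float = 0.05
    top_n_targets: int = 50
    min_module_size: int = 21
    min_abs_rho: float = 0.2
    k_min: int = 2
    k_max: int = 6
    n_resamples: int = 500
    subsample_fraction: float = 0.8
    delta_threshold: float = 0.05
    alpha: float = 0.25
    driver_scope: str = "all_nodes"
    seed: int = 0
    output_dir: str = "grndriver_run"

    def __post_init__(self) -> None:
        for name in ("auc_threshold", "top_fraction", "subsample_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1 and not (name == "subsample_fraction" and v == 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("k range must be ascending with k_min >= 2")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**(read_yaml(path) or {}))

    def to_yaml(self, path) -> None:
        write_yaml(self.to_dict(), path)
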
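"""Readers and writers for count matrices, gene sets, and fitted models.

Supported formats
-----------------
* 10x-style Matrix Market directory: ``matrix.mtx`` with ``features.tsv``
  and ``barcodes.tsv`` companions (gene rows, cell columns).
* Dense TSV count table: first column gene names, header row barcodes.
* GMT gene-set collections (name, description, member genes per line).
* Model artifacts: theta/phi TSV tables plus a JSON run manifest.

The in-memory convention throughout the package is genes x cells
(cells are the documents of the topic model, genes the words); readers
enforce that orientation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import FormatError, ValidationError

FLOAT_FORMAT = "%.6g"  # serialized precision for theta/phi; beyond sampler noise


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer counts with names attached.

    Parameters
    ----------
    counts
        2-D array, genes in rows, cells in columns; must be integer-valued
        and non-negative.
    gene_names, cell_barcodes
        Unique identifiers for rows and columns.
    cell_groups
        Optional per-cell condition label (e.g. treatment time point).
    """

    counts: np.ndarray
    gene_names: np.ndarray
    cell_barcodes: np.ndarray
    cell_groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError(f"counts must be 2-D, got shape {counts.shape}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64, copy=False)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if len(self.gene_names) != counts.shape[0]:
            raise ValidationError(
                f"{len(self.gene_names)} gene names for {counts.shape[0]} rows"
            )
        if len(self.cell_barcodes) != counts.shape[1]:
            raise ValidationError(
                f"{len(self.cell_barcodes)} barcodes for {counts.shape[1]} columns"
            )
        for label, names in (("gene_names", self.gene_names),
                             ("cell_barcodes", self.cell_barcodes)):
            if len(set(names)) != len(names):
                raise ValidationError(f"{label} are not unique")
        if self.cell_groups is not None:
            self.cell_groups = np.asarray(self.cell_groups, dtype=object)
            if len(self.cell_groups) != counts.shape[1]:
                raise ValidationError("cell_groups must have one label per barcode")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes) -> "CountMatrix":
        """Return a new matrix restricted to ``genes`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"genes not present in matrix: {missing[:5]}")
        rows = np.array([index[g] for g in genes], dtype=int)
        return CountMatrix(
            counts=self.counts[rows],
            gene_names=np.asarray(list(genes), dtype=object),
            cell_barcodes=self.cell_barcodes.copy(),
            cell_groups=None if self.cell_groups is None else self.cell_groups.copy(),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. factor-associated target genes from ChIP data)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def _read_name_column(path: Path) -> np.ndarray:
    """First column of a headerless TSV; 10x features files may carry an
    (id, symbol, type) triple, in which case the symbol column is used when
    its entries are unique, falling back to the id column otherwise."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if table.shape[1] >= 2:
        symbols = table.iloc[:, 1].to_numpy(dtype=object)
        if len(set(symbols)) == len(symbols):
            return symbols
    return table.iloc[:, 0].to_numpy(dtype=object)


def _find_companion(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        candidate = directory / stem
        if candidate.exists():
            return candidate
    raise FormatError(f"none of {stems} found in {directory}")


def read_counts(path, format: str = "mtx_dir") -> CountMatrix:
    """Read a count matrix.

    ``mtx_dir``: *path* is a directory holding ``matrix.mtx`` plus
    ``features.tsv`` (or ``genes.tsv``) and ``barcodes.tsv``.
    ``dense_tsv``: *path* is a TSV file, first column gene names, header
    row cell barcodes.
    """
    path = Path(path)
    if format == "mtx_dir":
        if not path.is_dir():
            raise FormatError(f"{path} is not a directory")
        mtx = _find_companion(path, ("matrix.mtx",))
        features = _find_companion(path, ("features.tsv", "genes.tsv"))
        barcodes = _find_companion(path, ("barcodes.tsv",))
        matrix = scipy.io.mmread(mtx)
        matrix = scipy.sparse.coo_matrix(matrix).toarray()
        data = matrix
        if not np.all(data == np.floor(data)):
            raise ValidationError(f"{mtx} has non-integer entries")
        if np.any(data < 0):
            raise ValidationError(f"{mtx} has negative entries")
        gene_names = _read_name_column(features)
        cell_barcodes = _read_name_column(barcodes)
        if matrix.shape[0] != len(gene_names):
            raise FormatError(
                f"matrix declares {matrix.shape[0]} genes but features file "
                f"has {len(gene_names)} rows"
            )
        if matrix.shape[1] != len(cell_barcodes):
            raise FormatError(
                f"matrix declares {matrix.shape[1]} cells but barcodes file "
                f"has {len(cell_barcodes)} rows"
            )
        groups = None
        groups_path = path / "groups.tsv"
        if groups_path.exists():
            groups = read_cell_groups(groups_path).reindex(cell_barcodes)
            if groups.isna().any():
                raise FormatError(f"{groups_path} missing labels for some barcodes")
            groups = groups.to_numpy(dtype=object)
        return CountMatrix(matrix.astype(np.int64), gene_names, cell_barcodes, groups)
    if format == "dense_tsv":
        table = pd.read_csv(path, sep="\t", index_col=0)
        values = table.to_numpy()
        return CountMatrix(
            values,
            table.index.to_numpy(dtype=object),
            table.columns.to_numpy(dtype=object),
        )
    raise ValidationError(f"unknown count-matrix format {format!r}")


def write_counts(matrix: CountMatrix, out_dir, format: str = "mtx_dir") -> Path:
    """Write a count matrix in a format :func:`read_counts` can read back."""
    out_dir = Path(out_dir)
    if out_dir.exists() and not out_dir.is_dir():
        raise IOError(f"{out_dir} exists and is not a directory")
    out_dir.mkdir(parents=True, exist_ok=True)
    if format == "mtx_dir":
        sparse = scipy.sparse.coo_matrix(matrix.counts)
        scipy.io.mmwrite(str(out_dir / "matrix.mtx"), sparse, field="integer")
        pd.Series(matrix.gene_names).to_csv(
            out_dir / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(matrix.cell_barcodes).to_csv(
            out_dir / "barcodes.tsv", sep="\t", header=False, index=False)
        if matrix.cell_groups is not None:
            pd.DataFrame({"barcode": matrix.cell_barcodes,
                          "group": matrix.cell_groups}).to_csv(
                out_dir / "groups.tsv", sep="\t", index=False)
        return out_dir
    if format == "dense_tsv":
        out = out_dir / "counts.tsv"
        pd.DataFrame(matrix.counts, index=matrix.gene_names,
                     columns=matrix.cell_barcodes).to_csv(out, sep="\t")
        return out
    raise ValidationError(f"unknown count-matrix format {format!r}")


def read_cell_groups(path) -> pd.Series:
    """Per-cell labels from a two-column TSV with header (barcode, group)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns (barcode, group)")
    return pd.Series(table.iloc[:, 1].to_numpy(dtype=object),
                     index=table.iloc[:, 0].to_numpy(dtype=object))


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene, got {len(fields)} fields"
                )
            name = fields[0].strip()
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [g.strip() for g in fields[2:] if g.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = fields[1]
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_model(model, out_dir, n_top: int = 50) -> Path:
    """Serialize a fitted topic model.

    Writes ``theta.tsv`` (cells x topics), ``phi.tsv`` (topics x genes),
    ``top_genes.tsv`` (rank-ordered signature per topic) and
    ``manifest.json`` (hyperparameters, seed, shapes). Values are written
    with 6 significant digits, beyond the sampler's noise floor, so a
    write/read round trip reproduces theta and phi at that precision.
    """
    from .topic_analysis import top_genes  # deferred: avoids import cycle

    out_dir = Path(out_dir)
    if out_dir.exists() and not out_dir.is_dir():
        raise IOError(f"{out_dir} exists and is not a directory")
    out_dir.mkdir(parents=True, exist_ok=True)
    topics = [f"Topic_{k}" for k in range(1, model.k + 1)]
    pd.DataFrame(model.theta, index=model.cell_barcodes, columns=topics).to_csv(
        out_dir / "theta.tsv", sep="\t", float_format=FLOAT_FORMAT)
    pd.DataFrame(model.phi, index=topics, columns=model.vocabulary).to_csv(
        out_dir / "phi.tsv", sep="\t", float_format=FLOAT_FORMAT)
    rows = []
    for topic in range(1, model.k + 1):
        signature = top_genes(model, topic, n=min(n_top, len(model.vocabulary)))
        for rank, gene in enumerate(signature.genes, start=1):
            rows.append((topic, rank, gene))
    pd.DataFrame(rows, columns=["topic", "rank", "gene"]).to_csv(
        out_dir / "top_genes.tsv", sep="\t", index=False)
    manifest = {
        "k": int(model.k),
        "alpha": float(model.alpha),
        "beta": float(model.beta),
        "alpha_mode": model.alpha_mode,
        "seed": int(model.seed),
        "iterations": int(model.iterations),
        "burn_in": int(model.burn_in),
        "n_cells": int(model.theta.shape[0]),
        "n_genes": int(model.phi.shape[1]),
    }
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return out_dir


def read_model(model_dir):
    """Load a model written by :func:`write_model`.

    Sampler count matrices are not serialized; the returned model carries
    theta/phi/vocabulary, which is sufficient for signatures, scoring,
    transfer, overlap and enrichment.
    """
    from .lda_engine import TopicModel  # deferred: avoids import cycle

    model_dir = Path(model_dir)
    with open(model_dir / "manifest.json") as handle:
        manifest = json.load(handle)
    theta = pd.read_csv(model_dir / "theta.tsv", sep="\t", index_col=0)
    phi = pd.read_csv(model_dir / "phi.tsv", sep="\t", index_col=0)
    return TopicModel(
        k=manifest["k"],
        alpha=manifest["alpha"],
        beta=manifest["beta"],
        alpha_mode=manifest.get("alpha_mode", "fixed"),
        theta=theta.to_numpy(),
        phi=phi.to_numpy(),
        vocabulary=phi.columns.to_numpy(dtype=object),
        cell_barcodes=theta.index.to_numpy(dtype=object),
        seed=manifest["seed"],
        iterations=manifest["iterations"],
        burn_in=manifest["burn_in"],
        counts_ck=None,
        counts_kg=None,
    )
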
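"""Core in-memory containers.

``CountMatrix`` is the nucleus/sample-level count container used
throughout the transcriptomic stages: a dense genes x units integer
matrix plus a per-unit metadata table (sample, genotype, sex, batch,
cell-type labels at three hierarchy levels, pool).

DE results travel as plain :class:`pandas.DataFrame` objects with the
column contract enforced by :func:`validate_de_table`.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import SchemaError

#: columns every DE table must carry
DE_COLUMNS = ("gene", "logFC", "pval", "padj", "baseMean")

#: metadata columns a CountMatrix knows about (missing ones are filled with defaults)
META_COLUMNS = ("sample", "genotype", "sex", "batch", "cell_type1", "cell_type2", "cell_type3", "pool")

CELL_TYPE_LEVELS = {1: "cell_type1", 2: "cell_type2", 3: "cell_type3"}


@dataclass
class CountMatrix:
    """Genes x units non-negative integer counts with per-unit metadata.

    Parameters
    ----------
    genes
        Ordered, unique gene identifiers (rows).
    counts
        ``(n_genes, n_units)`` array of non-negative integers.
    unit_meta
        One row per unit (column order of ``counts``); index holds the
        unit identifiers. Missing metadata columns are added with
        placeholder values.
    """

    genes: list[str]
    counts: np.ndarray
    unit_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise SchemaError("counts must be 2-D (genes x units)")
        n_genes, n_units = self.counts.shape
        if len(self.genes) != n_genes:
            raise SchemaError(f"{len(self.genes)} gene names for {n_genes} count rows")
        if len(set(self.genes)) != n_genes:
            raise SchemaError("duplicate gene identifiers")
        if self.unit_meta is None or len(self.unit_meta) == 0:
            self.unit_meta = pd.DataFrame(index=[f"unit{i}" for i in range(n_units)])
        if len(self.unit_meta) != n_units:
            raise SchemaError(f"{len(self.unit_meta)} metadata rows for {n_units} units")
        if self.unit_meta.index.has_duplicates:
            raise SchemaError("duplicate unit identifiers")
        if n_units and (not np.issubdtype(self.counts.dtype, np.integer)):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise SchemaError("counts must be integral")
            self.counts = np.round(self.counts).astype(np.int64)
        if n_units and self.counts.size and self.counts.min() < 0:
            raise SchemaError("counts must be non-negative")
        meta = self.unit_meta.copy()
        defaults = {
            "sample": [str(i) for i in meta.index],
            "genotype": "unknown",
            "sex": "unknown",
            "batch": "batch0",
            "cell_type1": "all",
            "cell_type2": "all",
            "cell_type3": "all",
            "pool": "pool0",
        }
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = defaults[col]
        self.unit_meta = meta

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    @property
    def units(self) -> list[str]:
        return [str(u) for u in self.unit_meta.index]

    def gene_index(self) -> pd.Index:
        return pd.Index(self.genes)

    def subset_units(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.genes, self.counts[:, mask], self.unit_meta.iloc[mask].copy())

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        idx = self.gene_index().get_indexer(genes)
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise SchemaError(f"genes not present: {missing[:5]}")
        return CountMatrix(list(genes), self.counts[idx], self.unit_meta.copy())

    # -- I/O -------------------------------------------------------------
    def write_mtx(self, outdir: str | os.PathLike, prefix: str = "counts") -> None:
        """Write MTX sparse counts with gene / unit-metadata TSV sidecars."""
        os.makedirs(outdir, exist_ok=True)
        scipy.io.mmwrite(os.path.join(outdir, f"{prefix}.mtx"), scipy.sparse.csr_matrix(self.counts))
        with open(os.path.join(outdir, f"{prefix}.genes.tsv"), "w") as fh:
            fh.write("\n".join(self.genes) + "\n")
        self.unit_meta.to_csv(os.path.join(outdir, f"{prefix}.units.tsv"), sep="\t", index_label="unit")

    @classmethod
    def read_mtx(cls, outdir: str | os.PathLike, prefix: str = "counts") -> "CountMatrix":
        counts = np.asarray(scipy.io.mmread(os.path.join(outdir, f"{prefix}.mtx")).todense())
        with open(os.path.join(outdir, f"{prefix}.genes.tsv")) as fh:
            genes = [line.strip() for line in fh if line.strip()]
        meta = pd.read_csv(os.path.join(outdir, f"{prefix}.units.tsv"), sep="\t", index_col="unit")
        meta.index = meta.index.astype(str)
        return cls(genes, counts.astype(np.int64), meta)

    def write_csv(self, path: str | os.PathLike) -> None:
        """Dense CSV with genes as rows and units as columns."""
        pd.DataFrame(self.counts, index=self.genes, columns=self.units).to_csv(path, index_label="gene")

    @classmethod
    def read_csv(cls, path: str | os.PathLike, meta_path: str | os.PathLike | None = None) -> "CountMatrix":
        df = pd.read_csv(path, index_col="gene")
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col="unit")
            meta.index = meta.index.astype(str)
        return cls(list(df.index), df.to_numpy(), meta if meta is not None else pd.DataFrame(index=df.columns))


def validate_de_table(de: pd.DataFrame) -> pd.DataFrame:
    """Check the DE-table column contract; returns the table unchanged."""
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise SchemaError(f"DE table missing columns: {missing}")
    return de


def write_de_table(de: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_de_table(de)
    de.loc[:, list(DE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    return validate_de_table(pd.read_csv(path, sep="\t"))


def write_json(obj, path: str | os.PathLike) -> None:
    class _Encoder(json.JSONEncoder):
        def default(self, o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return super().default(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_Encoder)
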
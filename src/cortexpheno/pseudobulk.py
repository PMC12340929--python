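"""Pseudobulk aggregation and the internal differential-expression engine.

Nucleus-level counts are summed to one column per sample within a cell
population, then tested gene-by-gene between genotypes on log2(CPM + 1)
values with a Welch two-sample t after least-squares removal of the
batch covariate, and Benjamini-Hochberg adjustment across the tested
genes.  The engine is deliberately simple and interchangeable: every
downstream stage (burden, module tests) accepts any externally produced
DE table with the gene/logFC/pval/padj/baseMean columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CELL_TYPE_LEVELS, CountMatrix
from .errors import DesignError, PopulationNotFoundError


@dataclass
class DesignSpec:
    """Two-group design: genotype contrast with optional covariates."""

    response: str = "genotype"
    levels: tuple = ("WT", "HET")          # (reference, test); logFC is test vs reference
    covariates: tuple = ("batch",)
    min_cpm: float = 1.0                   # expression filter: CPM >= min_cpm ...
    min_fraction: float = 0.5              # ... in >= this fraction of either group


def aggregate_pseudobulk(counts: CountMatrix, level: int, population: str) -> CountMatrix:
    """Sum nucleus counts to sample-level pseudobulk for one population.

    Samples contributing zero nuclei of the population are omitted.
    Sample metadata (genotype, sex, batch, pool) is carried over from
    the nuclei of the sample.
    """
    col = CELL_TYPE_LEVELS.get(level)
    if col is None:
        raise PopulationNotFoundError(f"unknown hierarchy level {level}")
    meta = counts.unit_meta
    mask = (meta[col] == population).to_numpy()
    if not mask.any():
        raise PopulationNotFoundError(f"population {population!r} not found at level {level}")
    sub = counts.counts[:, mask]
    sub_meta = meta.loc[mask]
    samples = sorted(sub_meta["sample"].unique())
    agg = np.zeros((counts.n_genes, len(samples)), dtype=np.int64)
    rows = []
    for j, s in enumerate(samples):
        sel = (sub_meta["sample"] == s).to_numpy()
        agg[:, j] = sub[:, sel].sum(axis=1)
        first = sub_meta.loc[sel].iloc[0]
        rows.append(
            {
                "sample": s,
                "genotype": first["genotype"],
                "sex": first["sex"],
                "batch": first["batch"],
                "pool": first["pool"],
                "n_units": int(sel.sum()),
            }
        )
    out_meta = pd.DataFrame(rows, index=pd.Index(samples, name="unit"))
    return CountMatrix(counts.genes, agg, out_meta)


def log_cpm(counts: np.ndarray, pseudocount: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Return (log2(CPM + pseudocount), CPM)."""
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise DesignError("sample with zero total counts")
    cpm = counts / lib * 1e6
    return np.log2(cpm + pseudocount), cpm


def _residualize_batch(y: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Least-squares removal of batch means per gene (adds back grand mean)."""
    levels = pd.unique(batch)
    if len(levels) < 2:
        return y
    out = y.copy()
    grand = y.mean(axis=1, keepdims=True)
    for b in levels:
        sel = batch == b
        out[:, sel] -= y[:, sel].mean(axis=1, keepdims=True) - grand
    return out


def welch_t(
    y: np.ndarray, mask_test: np.ndarray, mask_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-row Welch two-sample t (test vs reference).

    Returns (t, df, p); rows with zero variance in both groups get
    t = 0, p = 1.
    """
    n1, n2 = int(mask_test.sum()), int(mask_ref.sum())
    m1 = y[:, mask_test].mean(axis=1)
    m2 = y[:, mask_ref].mean(axis=1)
    v1 = y[:, mask_test].var(axis=1, ddof=1)
    v2 = y[:, mask_ref].var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    zero = se2 == 0
    t = np.zeros(y.shape[0])
    df = np.full(y.shape[0], n1 + n2 - 2.0)
    nz = ~zero
    t[nz] = (m1[nz] - m2[nz]) / np.sqrt(se2[nz])
    df_num = se2[nz] ** 2
    df_den = (v1[nz] / n1) ** 2 / (n1 - 1) + (v2[nz] / n2) ** 2 / (n2 - 1)
    df[nz] = df_num / df_den
    p = np.ones(y.shape[0])
    p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), df[nz])
    return t, df, p


@dataclass
class _DEInputs:
    """Label-invariant quantities precomputed once per pseudobulk matrix
    (reused across permutation iterations)."""

    genes: np.ndarray
    y: np.ndarray           # batch-residualized log2(CPM + 1)
    cpm: np.ndarray
    base_mean: np.ndarray   # mean CPM across all samples
    min_cpm: float = 1.0
    min_fraction: float = 0.5


def prepare_de_inputs(pseudobulk: CountMatrix, design: DesignSpec) -> _DEInputs:
    nonzero = pseudobulk.counts.sum(axis=1) > 0
    genes = np.asarray(pseudobulk.genes)[nonzero]
    counts = pseudobulk.counts[nonzero]
    y, cpm = log_cpm(counts)
    if "batch" in design.covariates:
        y = _residualize_batch(y, pseudobulk.unit_meta["batch"].to_numpy())
    return _DEInputs(genes, y, cpm, cpm.mean(axis=1), design.min_cpm, design.min_fraction)


def de_core(inputs: _DEInputs, mask_test: np.ndarray, mask_ref: np.ndarray) -> pd.DataFrame:
    """Run the expression filter + Welch test + BH for one labeling."""
    n1, n2 = int(mask_test.sum()), int(mask_ref.sum())
    expressed = inputs.cpm >= inputs.min_cpm
    need1 = int(np.ceil(inputs.min_fraction * n1))
    need2 = int(np.ceil(inputs.min_fraction * n2))
    keep = (expressed[:, mask_test].sum(axis=1) >= need1) | (expressed[:, mask_ref].sum(axis=1) >= need2)
    y = inputs.y[keep]
    t, df, p = welch_t(y, mask_test, mask_ref)
    logfc = y[:, mask_test].mean(axis=1) - y[:, mask_ref].mean(axis=1)
    padj = multipletests(p, method="fdr_bh")[1] if p.size else np.array([])
    return pd.DataFrame(
        {
            "gene": inputs.genes[keep],
            "logFC": logfc,
            "t": t,
            "df": df,
            "pval": p,
            "padj": padj,
            "baseMean": inputs.base_mean[keep],
        }
    )


def genotype_masks(meta: pd.DataFrame, design: DesignSpec) -> tuple[np.ndarray, np.ndarray]:
    labels = meta[design.response].to_numpy()
    ref, test = design.levels
    mask_ref = labels == ref
    mask_test = labels == test
    for name, mask in ((ref, mask_ref), (test, mask_test)):
        if mask.sum() < 2:
            raise DesignError(f"genotype level {name!r} has fewer than 2 samples")
    return mask_test, mask_ref


def de_test(pseudobulk: CountMatrix, design: DesignSpec | None = None) -> pd.DataFrame:
    """Per-gene differential expression between genotypes.

    Counts are CPM-normalized and log2(CPM + 1) transformed; the batch
    covariate is removed per gene by least squares; each gene passing
    the expression filter gets a Welch two-sample t between genotypes;
    logFC is the difference of group means of the log2 values (test
    minus reference); p-values are BH-adjusted across the tested genes;
    baseMean is the mean CPM across all samples.
    """
    design = design or DesignSpec()
    mask_test, mask_ref = genotype_masks(pseudobulk.unit_meta, design)
    inputs = prepare_de_inputs(pseudobulk, design)
    return de_core(inputs, mask_test, mask_ref)
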
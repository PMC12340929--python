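"""Co-expression module utilities.

Three operations on externally supplied gene -> module assignments (the
reserved label "grey" marks unassigned genes):

* :func:`module_score` — binned expression-matched control scoring of a
  gene set in each unit (cell/cluster), the standard way to compare a
  module's expression against a background of similarly expressed genes.
* :func:`annotate_clusters` — assign each cluster the marker module
  with the highest score.
* :func:`dem_test` — the differential-module-expression test: Welch t
  between the log2 fold changes of a module's genes and those of the
  grey genes, Bonferroni-corrected over all comparisons performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .containers import validate_de_table
from .errors import DesignError, SchemaError

logger = logging.getLogger(__name__)

GREY = "grey"


def read_module_map(path) -> pd.Series:
    """Two-column TSV (gene, module) -> gene-indexed Series of labels."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise SchemaError("module map must have gene and module columns")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def module_assignment_percentage(modules: pd.Series) -> float:
    """Percentage of genes assigned to a named (non-grey) module."""
    if len(modules) == 0:
        raise SchemaError("empty module map")
    return 100.0 * float((modules != GREY).sum()) / len(modules)


def module_score(
    expr: pd.DataFrame,
    module_genes,
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-matched module score per unit.

    ``expr`` is genes x units normalized expression.  Genes are placed
    in ``n_bins`` quantile bins of mean expression; for each module
    gene, ``n_controls`` non-module control genes are drawn from its
    bin (without replacement within a bin per module gene, bins reused
    across module genes); the score of a unit is the mean expression of
    the module genes minus the mean expression of the pooled controls.
    """
    if n_bins < 2:
        raise DesignError("n_bins must be >= 2")
    present = [g for g in module_genes if g in expr.index]
    dropped = [g for g in module_genes if g not in expr.index]
    if dropped:
        logger.warning("module_score: %d module genes absent from matrix", len(dropped))
    if not present:
        raise DesignError("no module gene present in the expression matrix")

    rng = child_rng(seed, "module_score")
    mean_expr = expr.mean(axis=1)
    # quantile bins of mean expression; duplicate edges collapse for ties
    bins = pd.qcut(mean_expr.rank(method="first"), q=n_bins, labels=False)
    module_set = set(present)

    controls: list[str] = []
    for g in present:
        pool = bins.index[(bins == bins[g]) & (~bins.index.isin(module_set))]
        if len(pool) == 0:
            continue
        take = min(n_controls, len(pool))
        controls.extend(rng.choice(pool.to_numpy(), size=take, replace=False).tolist())
    if not controls:
        raise DesignError("no control genes available for the module's expression bins")

    return expr.loc[present].mean(axis=0) - expr.loc[controls].mean(axis=0)


def annotate_clusters(
    cluster_expr: pd.DataFrame,
    marker_modules: dict,
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each cluster the marker module with the highest score.

    ``cluster_expr`` is genes x clusters mean expression; ties are
    broken lexicographically by module name and flagged.  Returns a
    frame indexed by cluster with columns label and tie.
    """
    if cluster_expr.shape[1] == 0:
        raise DesignError("empty cluster expression matrix")
    if not marker_modules:
        raise DesignError("need at least one marker module")
    names = sorted(marker_modules)
    scores = pd.DataFrame(
        {name: module_score(cluster_expr, marker_modules[name], n_bins, n_controls, seed) for name in names}
    )
    best = scores.max(axis=1)
    is_tie = (scores.eq(best, axis=0)).sum(axis=1) > 1
    label = scores.idxmax(axis=1)  # first (lexicographically smallest) argmax
    return pd.DataFrame({"label": label, "tie": is_tie, **{f"score_{n}": scores[n] for n in names}})


@dataclass
class DEMResult:
    module: str
    population: str
    median_logfc: float
    median_grey_logfc: float
    t: float
    pval: float
    padj: float
    n_module_genes: int
    direction: str


def dem_test(
    de: pd.DataFrame,
    modules: pd.Series,
    min_genes: int = 2,
    population: str = "all",
    one_sample: bool = False,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Differential module expression against the grey background.

    For each non-grey module with at least ``min_genes`` genes in the
    DE table, a Welch two-sample t compares the module genes' logFC
    values with the grey genes' logFC values (or, with ``one_sample``,
    a one-sample t against the grey median).  Medians of both
    distributions are reported for display; direction is the sign of
    their difference.  Bonferroni correction uses the number of tests
    performed in this invocation unless ``n_comparisons`` widens the
    universe (e.g. across populations).
    """
    validate_de_table(de)
    logfc = de.set_index("gene")["logFC"]
    grey_genes = modules.index[modules == GREY]
    grey = logfc.reindex(grey_genes).dropna()
    if len(grey) < 2:
        raise DesignError("grey module needs >= 2 genes with logFC values")

    rows = []
    for name in sorted(set(modules.unique()) - {GREY}):
        genes = modules.index[modules == name]
        vals = logfc.reindex(genes).dropna()
        if len(vals) < min_genes:
            logger.warning("dem_test: module %s has %d genes in the DE table; skipped", name, len(vals))
            continue
        if one_sample:
            t, p = stats.ttest_1samp(vals, grey.median())
        else:
            t, p = stats.ttest_ind(vals, grey, equal_var=False)
        med, med_grey = float(vals.median()), float(grey.median())
        rows.append(
            {
                "module": name,
                "population": population,
                "median_logfc": med,
                "median_grey_logfc": med_grey,
                "t": float(t),
                "pval": float(p),
                "n_module_genes": len(vals),
                "direction": "up" if med >= med_grey else "down",
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        m = n_comparisons if n_comparisons is not None else len(out)
        out["padj"] = np.minimum(1.0, out["pval"] * m)
        out = out[
            ["module", "population", "median_logfc", "median_grey_logfc",
             "t", "pval", "padj", "n_module_genes", "direction"]
        ]
    return out


def dem_test_populations(
    de_by_population: dict,
    modules: pd.Series,
    min_genes: int = 2,
    one_sample: bool = False,
) -> pd.DataFrame:
    """Run :func:`dem_test` across populations with a shared Bonferroni
    universe equal to the total number of (module x population) tests."""
    partial = [
        dem_test(de, modules, min_genes, pop, one_sample, n_comparisons=1)
        for pop, de in de_by_population.items()
    ]
    combined = pd.concat(partial, ignore_index=True)
    if len(combined):
        combined["padj"] = np.minimum(1.0, combined["pval"] * len(combined))
    return combined
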
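"""Sex classification, pool-design genotype inference, and cell-type
proportion models.

Nuclei from pooled samples carry no hashtag: sex is called from X/Y
marker expression (Y-linked genes vs Xist) and genotype follows from
the pool design, which pairs one male and one female of opposite
genotype per pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import CountMatrix
from .errors import DesignError, SchemaError

DEFAULT_Y_GENES = ("Ddx3y", "Uty", "Eif2s3y", "Kdm5d")
DEFAULT_X_INACTIVE = "Xist"


@dataclass
class PoolDesign:
    """pool id -> {"M": genotype, "F": genotype}; sexes carry opposite genotypes."""

    pools: dict

    def __post_init__(self) -> None:
        for pool, mapping in self.pools.items():
            if set(mapping) != {"M", "F"}:
                raise SchemaError(f"pool {pool!r} must map both sexes")
            if mapping["M"] == mapping["F"]:
                raise SchemaError(f"pool {pool!r} sexes must carry opposite genotypes")
            for g in mapping.values():
                if g not in ("WT", "HET"):
                    raise SchemaError(f"pool {pool!r} has unknown genotype {g!r}")

    def genotype(self, pool: str, sex: str) -> str | None:
        if pool not in self.pools:
            raise KeyError(f"pool {pool!r} absent from design")
        return self.pools[pool].get(sex)


def classify_sex(
    nuclei: CountMatrix,
    y_genes=DEFAULT_Y_GENES,
    x_inactive_gene: str = DEFAULT_X_INACTIVE,
    tau_y: int = 1,
    tau_x: int = 0,
    tau_x_prime: int = 1,
) -> pd.Series:
    """Rule-based per-nucleus sex call from marker counts.

    score_Y = total Y-linked marker counts, score_X = Xist counts;
    M if score_Y >= tau_y and score_X <= tau_x, F if score_X >=
    tau_x_prime and score_Y == 0, otherwise unknown.
    """
    gene_index = nuclei.gene_index()
    y_present = [g for g in y_genes if g in gene_index]
    if not y_present:
        raise SchemaError("no Y-linked marker gene present in the matrix")
    y_idx = gene_index.get_indexer(y_present)
    score_y = nuclei.counts[y_idx].sum(axis=0)
    if x_inactive_gene in gene_index:
        score_x = nuclei.counts[gene_index.get_loc(x_inactive_gene)]
    else:
        score_x = np.zeros(nuclei.n_units, dtype=np.int64)

    labels = np.full(nuclei.n_units, "unknown", dtype=object)
    labels[(score_y >= tau_y) & (score_x <= tau_x)] = "M"
    labels[(score_x >= tau_x_prime) & (score_y == 0)] = "F"
    return pd.Series(labels, index=nuclei.unit_meta.index, name="sex")


def assign_genotype(sex_labels: pd.Series, pool_of: pd.Series, design: PoolDesign) -> pd.Series:
    """Look up genotype from (pool, called sex); unknown sex stays unassigned."""
    missing = set(pool_of.unique()) - set(design.pools)
    if missing:
        raise KeyError(f"pools absent from design: {sorted(missing)}")
    out = pd.Series("unassigned", index=sex_labels.index, dtype=object, name="genotype")
    known = sex_labels.isin(["M", "F"])
    out[known] = [design.genotype(p, s) for p, s in zip(pool_of[known], sex_labels[known])]
    return out


def cell_type_proportions(counts_meta: pd.DataFrame, level_column: str = "cell_type2") -> pd.DataFrame:
    """Per-sample cell-type proportion table with sample covariates.

    ``counts_meta`` is the per-nucleus metadata; returns a frame indexed
    by sample with one proportion column per cell type plus genotype,
    sex, and batch covariates (taken from the sample's nuclei).
    """
    tab = pd.crosstab(counts_meta["sample"], counts_meta[level_column])
    props = tab.div(tab.sum(axis=1), axis=0)
    covars = counts_meta.groupby("sample")[["genotype", "sex", "batch"]].first()
    return props.join(covars)


def proportion_model(props: pd.DataFrame, cell_type: str, logit: bool = False) -> pd.DataFrame:
    """OLS of one cell type's proportion on genotype + sex + batch.

    Returns the coefficient table (estimate, SE, t, p) with two-sided
    t p-values at n - p degrees of freedom.  ``logit`` transforms the
    response for boundary-heavy data.
    """
    if cell_type not in props.columns:
        raise KeyError(f"cell type {cell_type!r} not in the proportion table")
    if len(props) < 4:
        raise DesignError("need >= 4 samples")
    y = props[cell_type].astype(float).to_numpy()
    if logit:
        eps = 1e-6
        y = np.log((y + eps) / (1 - y + eps))
    X = pd.DataFrame(index=props.index)
    X["Intercept"] = 1.0
    for col in ("genotype", "sex", "batch"):
        levels = sorted(props[col].astype(str).unique())
        for lev in levels[1:]:
            X[f"{col}[{lev}]"] = (props[col].astype(str) == lev).astype(float)
    Xm = X.to_numpy()
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        _, r = np.linalg.qr(Xm)
        aliased = [X.columns[i] for i in range(Xm.shape[1]) if abs(r[i, i]) < 1e-10]
        raise DesignError(f"rank-deficient design; aliased columns: {aliased}")
    fit = sm.OLS(y, Xm).fit()
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        },
        index=X.columns,
    )
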
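"""Cell-type DE-burden statistic and its permutation test.

Burden = 100 * (significant DEGs passing the expression floor) /
(expressed genes passing the floor).  The floor is the minimum baseMean
among genes with raw p < 0.05.  Significance of the observed burden is
assessed by permuting sample-level genotype labels (within batch when
batches are present) and rerunning the full DE + burden pipeline; when
the number of distinct label assignments is small the test enumerates
them all and reports an exact p.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .containers import CountMatrix, validate_de_table
from .errors import SchemaError, UndefinedStatisticError
from .pseudobulk import DesignSpec, de_core, genotype_masks, prepare_de_inputs


def min_expression_threshold(de: pd.DataFrame, p_cut: float = 0.05) -> float:
    """Minimum baseMean among genes with raw p below ``p_cut``.

    Returns 0 when no gene clears the p cut, so that every gene counts
    as expressed.
    """
    validate_de_table(de)
    if "baseMean" not in de.columns:
        raise SchemaError("DE table missing baseMean")
    hits = de.loc[de["pval"] < p_cut, "baseMean"]
    return float(hits.min()) if len(hits) else 0.0


def de_burden(
    de: pd.DataFrame,
    threshold: float,
    sig_column: str = "padj",
    sig_cut: float = 0.05,
) -> float:
    """Percentage of significant genes among expressed genes.

    ``threshold`` is the baseMean floor; the default significance rule
    is adjusted p < 0.05.
    """
    validate_de_table(de)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    expressed = de["baseMean"] >= threshold
    n_expressed = int(expressed.sum())
    if n_expressed == 0:
        raise UndefinedStatisticError("no expressed genes after the baseMean floor")
    n_sig = int((expressed & (de[sig_column] < sig_cut)).sum())
    return 100.0 * n_sig / n_expressed


@dataclass
class BurdenResult:
    population: str
    threshold: float
    n_expressed: int
    n_de: int
    burden: float
    perm_p: float
    n_perm: int
    exact: bool
    seed: int | None
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "population": self.population,
            "threshold": self.threshold,
            "n_expressed": self.n_expressed,
            "n_de": self.n_de,
            "burden": self.burden,
            "perm_p": self.perm_p,
            "n_perm": self.n_perm,
            "exact": self.exact,
            "seed": self.seed,
        }])


def _burden_from_core(de: pd.DataFrame, sig_cut: float, freeze_threshold: float | None) -> tuple[float, float, int, int]:
    thr = min_expression_threshold(de) if freeze_threshold is None else freeze_threshold
    expressed = de["baseMean"] >= thr
    n_expressed = int(expressed.sum())
    if n_expressed == 0:
        return 0.0, thr, 0, 0
    n_sig = int((expressed & (de["padj"] < sig_cut)).sum())
    return 100.0 * n_sig / n_expressed, thr, n_expressed, n_sig


def _assignments_within_strata(labels: np.ndarray, strata: np.ndarray):
    """All distinct genotype reassignments preserving per-stratum group sizes."""
    per_stratum = []
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        k = int(labels[idx].sum())
        per_stratum.append([set(c) for c in itertools.combinations(idx.tolist(), k)])
    for combo in itertools.product(*per_stratum):
        mask = np.zeros(labels.shape[0], dtype=bool)
        for chosen in combo:
            mask[list(chosen)] = True
        yield mask


def _count_assignments(labels: np.ndarray, strata: np.ndarray) -> int:
    total = 1
    for s in pd.unique(strata):
        idx = strata == s
        total *= math.comb(int(idx.sum()), int(labels[idx].sum()))
    return total


def burden_permutation_test(
    pseudobulk: CountMatrix,
    design: DesignSpec | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    population: str = "all",
    sig_cut: float = 0.05,
    within_batch: bool = True,
    freeze_threshold: bool = False,
) -> BurdenResult:
    """Permutation test of the observed DE burden.

    Genotype labels are shuffled across samples (within batch strata by
    default), the DE test and burden are recomputed per shuffle, and
    perm_p = (1 + #{permuted >= observed}) / (1 + n_iter).  When the
    number of distinct assignments does not exceed ``n_iter`` all of
    them are enumerated and the exact p (#{>= observed} / #assignments,
    observed included) is reported instead.  By default the baseMean
    floor is re-derived inside every permutation; ``freeze_threshold``
    pins it to the observed one.
    """
    design = design or DesignSpec()
    mask_test, mask_ref = genotype_masks(pseudobulk.unit_meta, design)
    inputs = prepare_de_inputs(pseudobulk, design)
    in_contrast = mask_test | mask_ref

    de_obs = de_core(inputs, mask_test, mask_ref)
    obs_burden, obs_thr, n_expressed, n_sig = _burden_from_core(de_obs, sig_cut, None)
    frozen = obs_thr if freeze_threshold else None

    strata = pseudobulk.unit_meta["batch"].to_numpy().copy()
    if not within_batch:
        strata = np.zeros(len(strata), dtype=int)
    strata = strata[in_contrast]
    labels = mask_test[in_contrast]
    idx_contrast = np.flatnonzero(in_contrast)

    warnings_list = []
    n_assign = _count_assignments(labels, strata)
    if n_assign < 20:
        warnings_list.append(f"only {n_assign} distinct label assignments; permutation p is coarse")

    def run(mask_sub: np.ndarray) -> float:
        mt = np.zeros(pseudobulk.n_units, dtype=bool)
        mt[idx_contrast[mask_sub]] = True
        mr = np.zeros(pseudobulk.n_units, dtype=bool)
        mr[idx_contrast[~mask_sub]] = True
        de = de_core(inputs, mt, mr)
        return _burden_from_core(de, sig_cut, frozen)[0]

    if n_assign <= n_iter:
        burdens = np.array([run(m) for m in _assignments_within_strata(labels, strata)])
        perm_p = float((burdens >= obs_burden - 1e-12).sum() / n_assign)
        return BurdenResult(population, obs_thr, n_expressed, n_sig, obs_burden,
                            perm_p, int(n_assign), True, seed, warnings_list)

    rng = child_rng(seed, "permutation")
    exceed = 0
    for _ in range(n_iter):
        mask_sub = np.zeros(len(labels), dtype=bool)
        for s in pd.unique(strata):
            idx = np.flatnonzero(strata == s)
            k = int(labels[idx].sum())
            mask_sub[rng.choice(idx, size=k, replace=False)] = True
        if run(mask_sub) >= obs_burden - 1e-12:
            exceed += 1
    perm_p = (1.0 + exceed) / (1.0 + n_iter)
    return BurdenResult(population, obs_thr, n_expressed, n_sig, obs_burden,
                        perm_p, n_iter, False, seed, warnings_list)
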
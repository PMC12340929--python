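"""Synthetic data generators with recorded ground truth.

Every downstream stage of the toolkit consumes the output of one of
these generators, so each records the planted truth it used: DE genes
with their signed log2 fold changes, module memberships and shifts,
per-nucleus sex and genotype, per-neuron event rasters and closed-form
expected pairwise correlations, Markov transition matrices, and the
exact cell count / volume of simulated tissue.

All randomness flows from a single seed through named
:mod:`~cortexpheno._rng` streams, so a fixed seed gives bit-identical
output for every generator independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .config import CalciumConfig, HypnogramConfig, SimConfig
from .containers import CountMatrix
from .errors import ConfigurationError
from .stereology import Box, Tissue

STATES = ("Wake", "NREM", "REM")


# ---------------------------------------------------------------------------
# negative binomial counts (pseudobulk samples)
# ---------------------------------------------------------------------------

@dataclass
class CountsTruth:
    """Planted truth for a simulated count matrix."""

    de_genes: dict = field(default_factory=dict)        # gene -> signed log2FC
    module_membership: dict = field(default_factory=dict)  # gene -> module name ("grey" = none)
    module_shift: dict = field(default_factory=dict)    # module -> genotype log2FC shift
    genotype: dict = field(default_factory=dict)        # sample -> genotype


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + mu^2 * dispersion (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_pseudobulk_counts(config: SimConfig) -> tuple[CountMatrix, CountsTruth]:
    """Simulate sample-level pseudobulk counts with genotype/batch structure.

    The model: per-gene relative abundances are log-normal; HET samples
    multiply planted DE genes by ``2**(+/- logfc_de)``; planted modules
    share a per-sample latent factor on the log2 scale and may carry
    their own genotype shift; per-(gene, batch) offsets model batch
    effects; counts are negative binomial around library-size-scaled
    means (var = mu + mu^2 * dispersion).
    """
    cc = config.counts
    cc.validate()
    rng = child_rng(config.seed, "counts")

    n_per = cc.n_samples_per_genotype
    samples = [f"WT{i+1}" for i in range(n_per)] + [f"HET{i+1}" for i in range(n_per)]
    genotype = ["WT"] * n_per + ["HET"] * n_per
    # balance batches within genotype
    batch = [f"batch{i % cc.n_batches}" for i in range(n_per)] * 2

    genes = [f"g{i:05d}" for i in range(cc.n_genes)]
    rel = np.exp(rng.normal(0.0, 1.2, size=cc.n_genes))

    truth = CountsTruth(genotype=dict(zip(samples, genotype)))
    truth.module_membership = {g: "grey" for g in genes}

    gene_pool = rng.permutation(cc.n_genes)
    cursor = 0

    n_de = int(round(cc.fraction_de * cc.n_genes))
    de_idx = gene_pool[cursor:cursor + n_de]
    cursor += n_de
    de_sign = rng.choice([-1.0, 1.0], size=n_de)
    log2fc = np.zeros(cc.n_genes)
    log2fc[de_idx] = de_sign * cc.logfc_de
    for i, s in zip(de_idx, de_sign):
        truth.de_genes[genes[i]] = float(s * cc.logfc_de)

    module_idx: dict[str, np.ndarray] = {}
    for mod in cc.modules:
        idx = gene_pool[cursor:cursor + mod.n_genes]
        if len(idx) < mod.n_genes:
            raise ConfigurationError("not enough genes to plant all modules and DE genes")
        cursor += mod.n_genes
        module_idx[mod.name] = idx
        truth.module_shift[mod.name] = float(mod.genotype_shift)
        for i in idx:
            truth.module_membership[genes[i]] = mod.name
            if mod.genotype_shift != 0:
                log2fc[i] += mod.genotype_shift
                truth.de_genes[genes[i]] = float(log2fc[i])

    lib_sizes = rng.uniform(*cc.lib_size_range, size=len(samples))
    batch_levels = sorted(set(batch))
    batch_offsets = rng.normal(0.0, cc.batch_effect_sd, size=(cc.n_genes, len(batch_levels)))
    latents = {m.name: rng.normal(0.0, 1.0, size=len(samples)) for m in cc.modules}

    counts = np.zeros((cc.n_genes, len(samples)), dtype=np.int64)
    for s_ix, (sample, geno, bt) in enumerate(zip(samples, genotype, batch)):
        log2_mult = batch_offsets[:, batch_levels.index(bt)].copy()
        if geno == "HET":
            log2_mult += log2fc
        for mod in cc.modules:
            log2_mult[module_idx[mod.name]] += mod.latent_sd * latents[mod.name][s_ix]
        expr = rel * np.exp2(log2_mult)
        mean = lib_sizes[s_ix] * expr / expr.sum()
        counts[:, s_ix] = _nb_draw(rng, mean, cc.dispersion)

    meta = pd.DataFrame(
        {"sample": samples, "genotype": genotype, "batch": batch},
        index=pd.Index(samples, name="unit"),
    )
    return CountMatrix(genes, counts, meta), truth


# ---------------------------------------------------------------------------
# sex-marker nuclei
# ---------------------------------------------------------------------------

@dataclass
class MarkersTruth:
    sex: pd.Series = None          # per-nucleus true sex ("M"/"F")
    genotype: pd.Series = None     # per-nucleus true genotype
    pool_design: dict = None       # pool -> {"M": genotype, "F": genotype}


def gen_nuclei_markers(config: SimConfig) -> tuple[CountMatrix, MarkersTruth]:
    """Simulate per-nucleus X/Y marker counts under the pooling design.

    Each pool holds one male and one female animal of opposite genotype;
    nuclei are assigned a pool and a sex, males get Poisson counts on the
    Y-linked markers and zero Xist, females the converse, and dropout
    independently zeroes each count with the stated probability.
    """
    mc = config.markers
    mc.validate()
    rng = child_rng(config.seed, "markers")

    pools = [f"pool{i+1}" for i in range(mc.n_pools)]
    # alternate which sex carries which genotype across pools
    pool_design = {
        p: ({"M": "WT", "F": "HET"} if i % 2 == 0 else {"M": "HET", "F": "WT"})
        for i, p in enumerate(pools)
    }

    genes = list(mc.y_genes) + [mc.x_inactive_gene] + [f"auto{i:02d}" for i in range(mc.n_background_genes)]
    n = mc.n_nuclei
    if n == 0:
        cm = CountMatrix(genes, np.zeros((len(genes), 0), dtype=np.int64), pd.DataFrame())
        return cm, MarkersTruth(pd.Series(dtype=object), pd.Series(dtype=object), pool_design)

    pool_of = rng.choice(pools, size=n)
    sex = rng.choice(["M", "F"], size=n)
    counts = np.zeros((len(genes), n), dtype=np.int64)
    male = sex == "M"
    n_y = len(mc.y_genes)
    counts[:n_y, male] = rng.poisson(mc.y_mean, size=(n_y, male.sum()))
    counts[n_y, ~male] = rng.poisson(mc.xist_mean, size=(~male).sum())
    counts[n_y + 1:, :] = rng.poisson(1.0, size=(mc.n_background_genes, n))
    if mc.dropout > 0:
        keep = rng.random(counts.shape) >= mc.dropout
        counts *= keep

    units = pd.Index([f"nucleus{i:05d}" for i in range(n)], name="unit")
    meta = pd.DataFrame({"sample": pool_of, "pool": pool_of}, index=units)
    genotype = np.array([pool_design[p][s] for p, s in zip(pool_of, sex)])
    truth = MarkersTruth(
        sex=pd.Series(sex, index=units),
        genotype=pd.Series(genotype, index=units),
        pool_design=pool_design,
    )
    return CountMatrix(genes, counts, meta), truth


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

@dataclass
class TraceSet:
    """Per-slice fluorescence data: raw traces, neuropil traces, depths."""

    traces: np.ndarray          # (n_neurons, n_frames) raw fluorescence
    neuropil: np.ndarray        # (n_neurons, n_frames)
    depths_um: np.ndarray       # (n_neurons,)
    frame_rate_hz: float
    slice_id: str = "slice0"
    animal_id: str = "animal0"
    genotype: str = "WT"


@dataclass
class CalciumTruth:
    raster: np.ndarray          # (n_neurons, n_frames) true binary event frames
    base_prob: np.ndarray       # per-neuron per-frame independent event probability
    factor_prob: np.ndarray     # (n_factors,) per-frame shared event probability
    loadings: np.ndarray        # (n_factors, n_neurons) acceptance probabilities
    kernel: np.ndarray          # transient decay kernel (dF/F units per event)

    def expected_activity(self, i: int) -> float:
        """P(frame active) for neuron ``i`` under the generative model."""
        miss = (1.0 - self.base_prob[i]) * np.prod(1.0 - self.factor_prob * self.loadings[:, i])
        return 1.0 - miss

    def expected_correlation(self, i: int, j: int) -> float:
        """Closed-form Pearson correlation of the binary frames of two neurons.

        Neuron frames are indicators X = B or (S_f and T_f) over shared
        factor events S_f thinned by the neuron's loading; independence
        across factors gives P(X_i=0, X_j=0) in product form.
        """
        pi, pj = self.expected_activity(i), self.expected_activity(j)
        li, lj = self.loadings[:, i], self.loadings[:, j]
        both_zero = (1.0 - self.base_prob[i]) * (1.0 - self.base_prob[j]) * np.prod(
            1.0 - self.factor_prob * (li + lj - li * lj)
        )
        e_xixj = 1.0 - (1.0 - pi) - (1.0 - pj) + both_zero
        cov = e_xixj - pi * pj
        denom = np.sqrt(pi * (1 - pi) * pj * (1 - pj))
        return float(cov / denom) if denom > 0 else 0.0


def _decay_kernel(cfg: CalciumConfig) -> np.ndarray:
    n = max(1, int(np.ceil(6 * cfg.decay_tau_s * cfg.frame_rate_hz)))
    t = np.arange(n) / cfg.frame_rate_hz
    return cfg.amplitude_dff * np.exp(-t / cfg.decay_tau_s)


def gen_calcium_traces(
    config: SimConfig,
    slice_id: str = "slice0",
    animal_id: str = "animal0",
    genotype: str = "WT",
    stream_index: int = 0,
) -> tuple[TraceSet, CalciumTruth]:
    """Simulate one slice of dF/F-like fluorescence traces.

    Each neuron's event train is a per-frame Bernoulli process (its own
    Poisson rate) plus shared latent-factor events accepted with a
    depth-bin-dependent loading; events are convolved with a
    single-exponential decay kernel, scaled onto a baseline, and white
    noise plus a neuropil component are added.  ``stream_index``
    separates the random streams of different slices.
    """
    cfg = config.calcium
    cfg.validate()
    rng = child_rng(config.seed, "calcium", stream_index)

    n, T = cfg.n_neurons, cfg.n_frames
    depths = rng.uniform(*cfg.depth_range_um, size=n)
    bin_width = (cfg.depth_range_um[1] - cfg.depth_range_um[0]) / 8.0

    base_p = np.full(n, min(1.0, cfg.event_rate_hz / cfg.frame_rate_hz))
    factors = cfg.latent_factors
    factor_p = np.array([min(1.0, f.rate_hz / cfg.frame_rate_hz) for f in factors])
    loadings = np.zeros((len(factors), n))
    for k, f in enumerate(factors):
        prof = np.asarray(f.loadings, dtype=float)
        bins = np.minimum((depths - cfg.depth_range_um[0]) // bin_width, len(prof) - 1).astype(int)
        loadings[k] = prof[bins]

    raster = rng.random((n, T)) < base_p[:, None]
    for k in range(len(factors)):
        shared = rng.random(T) < factor_p[k]
        accept = rng.random((n, T)) < loadings[k][:, None]
        raster |= shared[None, :] & accept

    kernel = _decay_kernel(cfg)
    dff = np.apply_along_axis(lambda r: np.convolve(r, kernel)[:T], 1, raster.astype(float))
    if cfg.noise_sd_dff > 0:
        dff = dff + rng.normal(0.0, cfg.noise_sd_dff, size=dff.shape)

    neuropil = cfg.neuropil_scale * cfg.baseline_f * (
        1.0 + 0.02 * np.cumsum(rng.normal(0, 1, size=(n, T)), axis=1) / np.sqrt(T)
    )
    traces = cfg.baseline_f * (1.0 + dff) + neuropil

    ts = TraceSet(traces, neuropil, depths, cfg.frame_rate_hz, slice_id, animal_id, genotype)
    truth = CalciumTruth(raster.astype(np.uint8), base_p, factor_p, loadings, kernel)
    return ts, truth


# ---------------------------------------------------------------------------
# hypnograms
# ---------------------------------------------------------------------------

def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 3-state transition matrix (left eigenvector)."""
    transition = np.asarray(transition, dtype=float)
    vals, vecs = np.linalg.eig(transition.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    return pi / pi.sum()


def gen_hypnogram(
    config: SimConfig,
    subject_id: str = "subject0",
    genotype: str = "WT",
    stream_index: int = 0,
    light_transition=None,
    dark_transition=None,
) -> pd.DataFrame:
    """Simulate a 24 h hypnogram as a first-order Markov chain.

    The transition matrix switches from the light-phase matrix to the
    dark-phase matrix at ZT12 (43,200 s).  Returns one row per scoring
    epoch with columns subject, genotype, start_s, duration_s, state;
    epochs tile [0, 86400) exactly.  Genotype-specific dynamics are
    modeled by passing modified transition matrices.
    """
    hc = config.hypnogram
    if light_transition is not None or dark_transition is not None:
        hc = HypnogramConfig(
            epoch_s=hc.epoch_s,
            light_transition=tuple(map(tuple, light_transition)) if light_transition is not None else hc.light_transition,
            dark_transition=tuple(map(tuple, dark_transition)) if dark_transition is not None else hc.dark_transition,
        )
    hc.validate()
    rng = child_rng(config.seed, "hypnogram", stream_index)

    light = np.asarray(hc.light_transition, dtype=float)
    dark = np.asarray(hc.dark_transition, dtype=float)
    n_epochs = 86_400 // hc.epoch_s
    switch_epoch = 43_200 // hc.epoch_s

    states = np.empty(n_epochs, dtype=np.int64)
    states[0] = rng.choice(3, p=stationary_distribution(light))
    for e in range(1, n_epochs):
        mat = light if e < switch_epoch else dark
        states[e] = rng.choice(3, p=mat[states[e - 1]])

    return pd.DataFrame(
        {
            "subject": subject_id,
            "genotype": genotype,
            "start_s": np.arange(n_epochs) * hc.epoch_s,
            "duration_s": hc.epoch_s,
            "state": [STATES[s] for s in states],
        }
    )


# ---------------------------------------------------------------------------
# tissue
# ---------------------------------------------------------------------------

def gen_tissue(config: SimConfig) -> Tissue:
    """Simulate a tissue block as a marked point process.

    Soma centers are uniform in a box of known volume; radii are normal,
    truncated away from zero.  The returned :class:`Tissue` carries the
    exact count and region volume as ground truth.
    """
    tc = config.tissue
    tc.validate()
    rng = child_rng(config.seed, "tissue")

    box = Box(*tc.box_um)
    centers = rng.uniform(0.0, 1.0, size=(tc.n_cells, 3)) * np.array(tc.box_um)
    radii = rng.normal(tc.radius_mean_um, tc.radius_sd_um, size=tc.n_cells)
    radii = np.clip(radii, 0.1, None)
    return Tissue(region=box, centers=centers, radii=radii)
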
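"""Simulation configuration.

One :class:`SimConfig` holds a global seed plus one parameter block per
generator.  Defaults mirror the design of the study the toolkit models:
5 HET vs 5 WT animals pooled two-per-pool with one male and one female
of opposite genotype, 10 Hz hour-long calcium recordings over a 600 um
cortical depth range, 24 h hypnograms with light/dark-dependent
dynamics, and tissue blocks with known neuron count and volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass

import numpy as np
import yaml

from .errors import ConfigurationError


@dataclass
class PlantedModule:
    """A planted co-expression module: genes share a latent factor and
    (optionally) a genotype logFC shift."""

    name: str
    n_genes: int = 80
    latent_sd: float = 0.25      # per-sample latent factor SD on log2 scale
    genotype_shift: float = 0.0  # log2FC added in HET samples


@dataclass
class CountsConfig:
    n_genes: int = 2000
    n_samples_per_genotype: int = 5
    n_batches: int = 2
    dispersion: float = 0.1          # var = mu + mu^2 * dispersion
    lib_size_range: tuple = (500_000.0, 1_500_000.0)
    batch_effect_sd: float = 0.15    # log2-scale gene x batch offset SD
    fraction_de: float = 0.0
    logfc_de: float = 1.0
    modules: list = field(default_factory=list)  # list[PlantedModule]

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ConfigurationError("n_genes must be >= 10")
        if self.n_samples_per_genotype < 2:
            raise ConfigurationError("need >= 2 samples per genotype")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")
        if not (0 <= self.fraction_de <= 1):
            raise ConfigurationError("fraction_de must be in [0, 1]")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("invalid library-size range")


@dataclass
class MarkersConfig:
    n_nuclei: int = 2000
    n_pools: int = 2
    y_genes: tuple = ("Ddx3y", "Uty", "Eif2s3y", "Kdm5d")
    x_inactive_gene: str = "Xist"
    y_mean: float = 2.0              # Poisson mean per Y-linked gene in males
    xist_mean: float = 8.0           # Poisson mean of Xist in females
    dropout: float = 0.0             # per-count zeroing probability
    n_background_genes: int = 20     # autosomal filler genes

    def validate(self) -> None:
        if not (0 <= self.dropout <= 1):
            raise ConfigurationError("dropout must be in [0, 1]")
        if self.y_mean < 0 or self.xist_mean < 0:
            raise ConfigurationError("marker means must be non-negative")
        if len(self.y_genes) < 1:
            raise ConfigurationError("need >= 1 Y-linked marker gene")


@dataclass
class LatentFactor:
    """Shared event source with depth-dependent loadings.

    ``loadings`` has one probability per depth bin: the chance that a
    neuron in that bin expresses each shared event.
    """

    rate_hz: float = 0.3
    loadings: tuple = (1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class CalciumConfig:
    n_neurons: int = 60
    depth_range_um: tuple = (0.0, 600.0)
    frame_rate_hz: float = 10.0
    n_frames: int = 36_000
    event_rate_hz: float = 0.005     # per-neuron independent event rate (sparse slice activity)
    latent_factors: list = field(default_factory=list)  # list[LatentFactor]
    amplitude_dff: float = 4.0       # transient peak in dF/F units
    decay_tau_s: float = 1.25
    noise_sd_dff: float = 0.03
    baseline_f: float = 100.0
    neuropil_scale: float = 0.3

    def validate(self) -> None:
        if self.n_frames < 100:
            raise ConfigurationError("duration must be >= 100 frames")
        if self.event_rate_hz < 0 or any(f.rate_hz < 0 for f in self.latent_factors):
            raise ConfigurationError("event rates must be non-negative")
        lo, hi = self.depth_range_um
        if lo < 0 or hi <= lo:
            raise ConfigurationError("invalid depth range")
        for f in self.latent_factors:
            if any(not (0 <= l <= 1) for l in f.loadings):
                raise ConfigurationError("latent loadings are probabilities in [0, 1]")


_DEFAULT_LIGHT = ((0.90, 0.098, 0.002), (0.06, 0.90, 0.04), (0.10, 0.10, 0.80))
_DEFAULT_DARK = ((0.96, 0.038, 0.002), (0.12, 0.85, 0.03), (0.15, 0.10, 0.75))


@dataclass
class HypnogramConfig:
    epoch_s: int = 10
    # row/col order: Wake, NREM, REM
    light_transition: tuple = _DEFAULT_LIGHT
    dark_transition: tuple = _DEFAULT_DARK

    def validate(self) -> None:
        if 3600 % self.epoch_s != 0:
            raise ConfigurationError("epoch length must divide 3600 s")
        for name, mat in (("light", self.light_transition), ("dark", self.dark_transition)):
            arr = np.asarray(mat, dtype=float)
            if arr.shape != (3, 3):
                raise ConfigurationError(f"{name} transition matrix must be 3x3")
            if (arr < 0).any() or not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigurationError(f"{name} transition matrix rows must sum to 1")


@dataclass
class TissueConfig:
    box_um: tuple = (400.0, 400.0, 200.0)
    n_cells: int = 10_000
    radius_mean_um: float = 6.0
    radius_sd_um: float = 1.0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("true count must be >= 1")
        if any(d <= 0 for d in self.box_um):
            raise ConfigurationError("box dimensions must be positive")
        if self.radius_mean_um <= 0 or self.radius_sd_um < 0:
            raise ConfigurationError("soma radius distribution must have positive support")


@dataclass
class SimConfig:
    seed: int = 0
    counts: CountsConfig = field(default_factory=CountsConfig)
    markers: MarkersConfig = field(default_factory=MarkersConfig)
    calcium: CalciumConfig = field(default_factory=CalciumConfig)
    hypnogram: HypnogramConfig = field(default_factory=HypnogramConfig)
    tissue: TissueConfig = field(default_factory=TissueConfig)

    def validate(self) -> "SimConfig":
        for block in (self.counts, self.markers, self.calcium, self.hypnogram, self.tissue):
            block.validate()
        return self


_BLOCK_TYPES = {
    "counts": CountsConfig,
    "markers": MarkersConfig,
    "calcium": CalciumConfig,
    "hypnogram": HypnogramConfig,
    "tissue": TissueConfig,
}


def _build(cls, data: dict):
    valid = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(valid)
    if unknown:
        raise ConfigurationError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key == "modules" and isinstance(value, list):
            value = [v if isinstance(v, PlantedModule) else _build(PlantedModule, v) for v in value]
        elif key == "latent_factors" and isinstance(value, list):
            value = [v if isinstance(v, LatentFactor) else _build(LatentFactor, v) for v in value]
        elif isinstance(value, list) and not is_dataclass(valid[key].type):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def load_sim_config(path_or_dict) -> SimConfig:
    """Build a validated :class:`SimConfig` from a YAML file or dict.

    Unknown keys are rejected so typos never silently fall back to
    defaults.
    """
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(_BLOCK_TYPES) - {"seed"}
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    cfg = SimConfig(seed=int(data.get("seed", 0)))
    for name, cls in _BLOCK_TYPES.items():
        if name in data:
            setattr(cfg, name, _build(cls, data[name] or {}))
    return cfg.validate()
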
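"""Design-based stereology: Cavalieri volume, optical-fractionator
counts, and nucleator soma volumes.

All three estimators are unbiased under systematic uniform random
sampling: sections start at a uniform random offset within one sampling
interval, counting frames sit on a uniformly offset grid, and nucleator
rays are isotropic.  The synthetic :class:`Tissue` substrate records its
exact cell count and region volume so unbiasedness can be verified by
simulation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .errors import ConfigurationError, UndefinedStatisticError


# ---------------------------------------------------------------------------
# regions and tissue
# ---------------------------------------------------------------------------

@dataclass
class Box:
    """Axis-aligned box [0,lx] x [0,ly] x [0,lz] (um)."""

    lx: float
    ly: float
    lz: float

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz

    @property
    def z_range(self) -> tuple[float, float]:
        return (0.0, self.lz)

    def cross_section_area(self, z: float) -> float:
        return self.lx * self.ly if 0.0 <= z < self.lz else 0.0

    def contains_xy(self, x: np.ndarray, y: np.ndarray, z: float) -> np.ndarray:
        inside_z = 0.0 <= z < self.lz
        return inside_z & (x >= 0) & (x < self.lx) & (y >= 0) & (y < self.ly)

    def xy_bounds(self) -> tuple[float, float, float, float]:
        return (0.0, self.lx, 0.0, self.ly)


@dataclass
class Sphere:
    """Sphere of radius r centered at (r, r, r) so it sits in the positive octant."""

    r: float

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.r**3

    @property
    def z_range(self) -> tuple[float, float]:
        return (0.0, 2.0 * self.r)

    def cross_section_area(self, z: float) -> float:
        h = z - self.r
        if abs(h) >= self.r:
            return 0.0
        return float(np.pi * (self.r**2 - h**2))

    def contains_xy(self, x: np.ndarray, y: np.ndarray, z: float) -> np.ndarray:
        h = z - self.r
        r2 = self.r**2 - h**2
        if r2 <= 0:
            return np.zeros(np.shape(x), dtype=bool)
        return (x - self.r) ** 2 + (y - self.r) ** 2 < r2

    def xy_bounds(self) -> tuple[float, float, float, float]:
        return (0.0, 2 * self.r, 0.0, 2 * self.r)


@dataclass
class Tissue:
    """3D soma point process with radii inside a bounded region.

    ``true_count`` and ``true_volume`` are exact by construction and
    serve as the reference the estimators are validated against.
    """

    region: Box | Sphere
    centers: np.ndarray   # (n, 3) um
    radii: np.ndarray     # (n,) um

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if (self.radii <= 0).any():
            raise ConfigurationError("soma radii must be positive")

    @property
    def true_count(self) -> int:
        return self.centers.shape[0]

    @property
    def true_volume(self) -> float:
        return self.region.volume

    def true_soma_volumes(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * self.radii**3

    # -- I/O -------------------------------------------------------------
    def write(self, csv_path: str | os.PathLike, truth_path: str | os.PathLike) -> None:
        pd.DataFrame(
            {"x": self.centers[:, 0], "y": self.centers[:, 1], "z": self.centers[:, 2], "radius": self.radii}
        ).to_csv(csv_path, index=False)
        truth = {"true_count": self.true_count, "true_volume": self.true_volume}
        if isinstance(self.region, Box):
            truth["region"] = {"kind": "box", "lx": self.region.lx, "ly": self.region.ly, "lz": self.region.lz}
        else:
            truth["region"] = {"kind": "sphere", "r": self.region.r}
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)

    @classmethod
    def read(cls, csv_path: str | os.PathLike, truth_path: str | os.PathLike) -> "Tissue":
        df = pd.read_csv(csv_path)
        with open(truth_path) as fh:
            truth = json.load(fh)
        reg = truth["region"]
        region = Box(reg["lx"], reg["ly"], reg["lz"]) if reg["kind"] == "box" else Sphere(reg["r"])
        return cls(region, df[["x", "y", "z"]].to_numpy(), df["radius"].to_numpy())


# ---------------------------------------------------------------------------
# section sampling and Cavalieri
# ---------------------------------------------------------------------------

@dataclass
class SectionSeries:
    """Systematically spaced z-sections with a uniform random start."""

    z_positions: np.ndarray      # slab start positions (um)
    interval_um: float           # d
    thickness_um: float          # t
    start_offset_um: float       # uniform in [0, d)
    areas_um2: np.ndarray        # exact cross-section area at each section plane
    point_counts: np.ndarray | None = None   # point-counting record, if used
    area_per_point_um2: float | None = None


def sample_sections(
    tissue_or_region,
    d: float,
    t: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    point_spacing_um: float | None = None,
) -> SectionSeries:
    """Sample systematic z-sections with a random start in [0, d).

    Records the exact cross-sectional area of the region at every
    section plane; when ``point_spacing_um`` is given, a uniformly
    offset point grid is also overlaid on each plane and hits are
    counted (Cavalieri point-counting mode).
    """
    region = tissue_or_region.region if isinstance(tissue_or_region, Tissue) else tissue_or_region
    if not (d >= t > 0):
        raise ConfigurationError("need d >= t > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    z_lo, z_hi = region.z_range
    if z_hi - z_lo < d:
        # degenerate design: guarantee the single section lands inside the
        # region (random within its extent) instead of possibly missing it
        import warnings

        warnings.warn("region thinner than the sampling interval; single section")
        u = rng.uniform(0.0, z_hi - z_lo)
        z = np.array([z_lo + u])
    else:
        u = rng.uniform(0.0, d)
        z = np.arange(z_lo + u, z_hi, d)
    areas = np.array([region.cross_section_area(zk) for zk in z])

    point_counts = None
    app = None
    if point_spacing_um is not None:
        s = point_spacing_um
        app = s * s
        x0, x1, y0, y1 = region.xy_bounds()
        ox, oy = rng.uniform(0.0, s, size=2)
        gx = np.arange(x0 - s + ox, x1 + s, s)
        gy = np.arange(y0 - s + oy, y1 + s, s)
        xx, yy = np.meshgrid(gx, gy)
        point_counts = np.array([int(region.contains_xy(xx, yy, zk).sum()) for zk in z])
    return SectionSeries(z, d, t, u, areas, point_counts, app)


def cavalieri_volume(series: SectionSeries, mode: str = "area") -> float:
    """Cavalieri estimator V = d * sum(A_i) (or d * a/p * sum(P_i))."""
    if mode == "area":
        if series.areas_um2 is None or series.areas_um2.size == 0:
            raise UndefinedStatisticError("no section areas recorded")
        return float(series.interval_um * series.areas_um2.sum())
    if mode == "point":
        if series.point_counts is None:
            raise UndefinedStatisticError("no point counts recorded; sample with point_spacing_um")
        return float(series.interval_um * series.area_per_point_um2 * series.point_counts.sum())
    raise ConfigurationError(f"unknown Cavalieri mode {mode!r}")


# ---------------------------------------------------------------------------
# optical fractionator
# ---------------------------------------------------------------------------

@dataclass
class FractionatorSpec:
    """Sampling design for the optical fractionator.

    Defaults follow a standard cortical design: an 18 x 18 um counting
    frame with a 10 um dissector and 2 um guard zones inside 60 um
    sections sampled every 480 um on a 480 x 480 um scan grid.
    """

    frame_x_um: float = 18.0
    frame_y_um: float = 18.0
    dissector_h_um: float = 10.0
    guard_um: float = 2.0
    grid_x_um: float = 480.0
    grid_y_um: float = 480.0
    section_interval_um: float = 480.0
    section_thickness_um: float = 60.0
    rotate_grid: bool = False

    def validate(self) -> None:
        if self.dissector_h_um + 2 * self.guard_um > self.section_thickness_um:
            raise ConfigurationError("dissector plus guard zones must fit in the section")
        if self.frame_x_um > self.grid_x_um or self.frame_y_um > self.grid_y_um:
            raise ConfigurationError("counting frame must fit in the grid cell")
        for f in (self.ssf, self.asf, self.nominal_tsf):
            if not (0 < f <= 1):
                raise ConfigurationError("sampling fractions must be in (0, 1]")

    @property
    def ssf(self) -> float:
        return self.section_thickness_um / self.section_interval_um

    @property
    def asf(self) -> float:
        return (self.frame_x_um * self.frame_y_um) / (self.grid_x_um * self.grid_y_um)

    @property
    def nominal_tsf(self) -> float:
        return self.dissector_h_um / self.section_thickness_um


@dataclass
class FractionatorResult:
    n_hat: float
    q_minus: int
    ssf: float
    asf: float
    tsf: float
    mean_measured_thickness_um: float
    n_sections: int


def optical_fractionator_count(
    tissue: Tissue,
    spec: FractionatorSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> FractionatorResult:
    """Optical fractionator estimate of total cell number.

    The unique counting point of each soma is its topmost z (a nucleolus
    surrogate).  Sections of thickness t tile z with period d from a
    uniform random start; within a section the point is counted iff it
    falls in the dissector [z+g, z+g+h) and inside a counting frame of a
    uniformly offset grid (half-open frame intervals implement the
    forbidden left/lower exclusion edges).  N = Q- / (ssf * asf * tsf),
    with tsf from thickness measured at counting sites.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(seed)

    d = spec.section_interval_um
    u = rng.uniform(0.0, d)
    ox = rng.uniform(0.0, spec.grid_x_um)
    oy = rng.uniform(0.0, spec.grid_y_um)

    top = tissue.centers[:, 2] + tissue.radii
    x, y = tissue.centers[:, 0], tissue.centers[:, 1]
    if spec.rotate_grid:
        theta = rng.uniform(0.0, 2 * np.pi)
        cx = 0.5 * (tissue.region.xy_bounds()[0] + tissue.region.xy_bounds()[1])
        cy = 0.5 * (tissue.region.xy_bounds()[2] + tissue.region.xy_bounds()[3])
        ct, st = np.cos(theta), np.sin(theta)
        x, y = cx + ct * (x - cx) - st * (y - cy), cy + st * (x - cx) + ct * (y - cy)

    z_lo = tissue.region.z_range[0]
    # position of each counting point within its section, via the tiling period
    in_section = (top - z_lo - u) % d
    in_dissector = (in_section >= spec.guard_um) & (in_section < spec.guard_um + spec.dissector_h_um)
    in_frame_x = (x - ox) % spec.grid_x_um < spec.frame_x_um
    in_frame_y = (y - oy) % spec.grid_y_um < spec.frame_y_um
    counted = in_dissector & in_frame_x & in_frame_y

    q = int(counted.sum())
    # synthetic sections cut at exactly nominal thickness, so every
    # site measurement returns t; the site-weighted mean follows
    t_bar = spec.section_thickness_um
    tsf = spec.dissector_h_um / t_bar
    n_hat = q / (spec.ssf * spec.asf * tsf)
    z_hi = max(tissue.region.z_range[1], float(top.max()) if top.size else 0.0)
    n_sections = int(np.ceil((z_hi - z_lo - u) / d)) + 1
    return FractionatorResult(n_hat, q, spec.ssf, spec.asf, tsf, t_bar, n_sections)


# ---------------------------------------------------------------------------
# nucleator
# ---------------------------------------------------------------------------

def sphere_radial(r: float):
    """Radial boundary function of a sphere about its center."""

    def radial(directions: np.ndarray) -> np.ndarray:
        return np.full(directions.shape[0], float(r))

    return radial


def ellipsoid_radial(a: float, b: float, c: float):
    """Radial boundary function of an axis-aligned ellipsoid about its center."""

    def radial(directions: np.ndarray) -> np.ndarray:
        dx, dy, dz = directions[:, 0], directions[:, 1], directions[:, 2]
        return 1.0 / np.sqrt((dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2)

    return radial


def isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def nucleator_volume(
    radial,
    n_rays: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Nucleator estimator v = (4 pi / 3) * mean(l^3) over isotropic rays.

    ``radial`` maps an (n, 3) array of unit direction vectors to the
    distance from the reference point to the boundary along each ray
    (nearest intersection for non-star-shaped profiles).
    """
    if n_rays < 1:
        raise ConfigurationError("n_rays must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = np.asarray(radial(isotropic_directions(n_rays, rng)), dtype=float)
    if (lengths < 0).any():
        raise ConfigurationError("radial function returned a negative length")
    return float(4.0 / 3.0 * np.pi * np.mean(lengths**3))


def soma_volume_nucleator(
    tissue: Tissue,
    n_rays: int = 6,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-soma nucleator volume estimates (exact for the spherical somas)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return np.array([nucleator_volume(sphere_radial(r), n_rays, rng=rng) for r in tissue.radii])
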
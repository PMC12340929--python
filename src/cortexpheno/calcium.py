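"""Calcium trace processing and microcircuit correlation analysis.

The pipeline starts from extracted per-neuron fluorescence traces:
neuropil subtraction, FIR lowpass filtering, dF/F conversion,
threshold-based event detection (2.5-sigma one-frame rise, kept only if
the event peaks at >= 8 sigma and integrates to >= 200 sigma), binary
raster construction, depth-binned pairwise correlation matrices
(eight 75 um bins from the cortical surface by default), and
slice-level genotype comparisons.  Dendritic-spine turnover metrics
from longitudinal imaging live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import ConfigurationError, DesignError


# ---------------------------------------------------------------------------
# trace conditioning
# ---------------------------------------------------------------------------

def neuropil_subtract(trace: np.ndarray, neuropil_trace: np.ndarray) -> np.ndarray:
    """Elementwise cell-minus-neuropil correction."""
    trace = np.asarray(trace, dtype=float)
    neuropil_trace = np.asarray(neuropil_trace, dtype=float)
    if trace.shape != neuropil_trace.shape:
        raise ConfigurationError("trace and neuropil trace must have equal length")
    return trace - neuropil_trace


def design_lowpass(
    passband: float = 0.5,
    stopband: float = 0.65,
    stopband_atten_db: float = 25.0,
) -> np.ndarray:
    """Linear-phase FIR lowpass taps for the stated band edges.

    Frequencies are normalized to Nyquist (so 0.5 -> 2.5 Hz at 10 Hz
    sampling).  A Kaiser window sized for the attenuation and
    transition width is used; DC gain is unity.
    """
    if not (0 < passband < stopband < 1):
        raise ConfigurationError("need 0 < passband < stopband < 1")
    numtaps, beta = signal.kaiserord(stopband_atten_db, stopband - passband)
    numtaps |= 1  # odd length keeps the filter type-I linear phase
    return signal.firwin(numtaps, (passband + stopband) / 2.0, window=("kaiser", beta))


def lowpass(
    trace: np.ndarray,
    passband: float = 0.5,
    stopband: float = 0.65,
    stopband_atten_db: float = 25.0,
) -> np.ndarray:
    """Zero-phase (forward-backward) FIR lowpass of one trace."""
    taps = design_lowpass(passband, stopband, stopband_atten_db)
    trace = np.asarray(trace, dtype=float)
    padlen = 3 * len(taps)
    if trace.size <= padlen:
        raise ConfigurationError(f"trace shorter than filter requirements ({padlen + 1} frames)")
    return signal.filtfilt(taps, [1.0], trace)


def dff(trace: np.ndarray, baseline_method: str = "percentile", percentile: float = 20.0,
        window_frames: int | None = None) -> tuple[np.ndarray, float]:
    """Convert a corrected trace to (F - F0)/F0 and return its sigma.

    Default baseline is the 20th percentile of the full trace; a
    rolling-percentile alternative is available via ``window_frames``.
    sigma is the standard deviation of the dF/F trace.
    """
    trace = np.asarray(trace, dtype=float)
    if baseline_method == "percentile":
        if window_frames:
            s = pd.Series(trace)
            f0 = s.rolling(window_frames, min_periods=1, center=True).quantile(percentile / 100.0).to_numpy()
        else:
            f0 = np.percentile(trace, percentile)
    else:
        raise ConfigurationError(f"unknown baseline method {baseline_method!r}")
    if np.min(f0) <= 0:
        raise ConfigurationError("baseline F0 must be positive; trace rejected")
    d = (trace - f0) / f0
    return d, float(np.std(d))


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

@dataclass
class Event:
    onset: int
    end: int      # exclusive
    peak: float
    area: float


def detect_events(
    dff_trace: np.ndarray,
    sigma: float,
    onset_mult: float = 2.5,
    peak_mult: float = 8.0,
    area_mult: float = 200.0,
    end_mult: float = 0.5,
) -> tuple[list[Event], np.ndarray]:
    """Threshold-based transient detection on one dF/F trace.

    Candidate onsets are frames whose one-frame dF/F increase exceeds
    ``onset_mult`` * sigma; a candidate grows until dF/F falls below
    ``end_mult`` * sigma (overlapping candidates merge); the event is
    kept iff its peak reaches ``peak_mult`` * sigma and its summed dF/F
    reaches ``area_mult`` * sigma (sigma-frames at the native rate).
    Returns the kept events and the binary raster row.
    """
    dff_trace = np.asarray(dff_trace, dtype=float)
    raster = np.zeros(dff_trace.size, dtype=np.uint8)
    if sigma <= 0:
        return [], raster
    rise = np.diff(dff_trace, prepend=dff_trace[:1])
    onsets = np.flatnonzero(rise > onset_mult * sigma)
    events: list[Event] = []
    cursor = 0
    for onset in onsets:
        if onset < cursor:
            continue  # inside the previous event: merged
        end = onset
        while end < dff_trace.size and dff_trace[end] >= end_mult * sigma:
            end += 1
        if end == onset:
            end = onset + 1  # onset frame itself below the floor: 1-frame candidate
        seg = dff_trace[onset:end]
        peak, area = float(seg.max()), float(seg.sum())
        if peak >= peak_mult * sigma and area >= area_mult * sigma:
            events.append(Event(int(onset), int(end), peak, area))
            raster[onset:end] = 1
        cursor = end
    return events, raster


def fraction_active(raster_row: np.ndarray) -> float:
    """Active frames / total frames."""
    raster_row = np.asarray(raster_row)
    if raster_row.size == 0:
        raise ConfigurationError("raster row must have >= 1 frame")
    return float(raster_row.sum() / raster_row.size)


def traces_to_raster(
    traces: np.ndarray,
    neuropil: np.ndarray | None = None,
    apply_lowpass: bool = True,
    **detect_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Full conditioning chain for a slice: returns (raster, sigmas)."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    corrected = traces if neuropil is None else neuropil_subtract(traces, neuropil)
    raster = np.zeros(corrected.shape, dtype=np.uint8)
    sigmas = np.zeros(corrected.shape[0])
    for i, row in enumerate(corrected):
        f = lowpass(row) if apply_lowpass else row
        d, s = dff(f)
        _, raster[i] = detect_events(d, s, **detect_kwargs)
        sigmas[i] = s
    return raster, sigmas


# ---------------------------------------------------------------------------
# depth-binned correlation
# ---------------------------------------------------------------------------

@dataclass
class BinCorrMatrix:
    """Mean pairwise correlation per depth-bin pair for one slice."""

    matrix: np.ndarray        # (n_bins, n_bins), NaN where no pair contributed
    pair_counts: np.ndarray   # (n_bins, n_bins)
    bin_edges_um: np.ndarray  # length n_bins + 1
    slice_id: str = "slice0"
    genotype: str = "WT"
    n_excluded_depth: int = 0
    n_zero_variance_pairs: int = 0


def depth_bin_correlation(
    raster: np.ndarray,
    depths_um: np.ndarray,
    bin_width_um: float = 75.0,
    n_bins: int = 8,
    slice_id: str = "slice0",
    genotype: str = "WT",
) -> BinCorrMatrix:
    """Average pairwise Pearson correlation of event rasters by depth bin.

    Every unordered neuron pair contributes its correlation to the
    (bin_i, bin_j) and (bin_j, bin_i) cells; cell values are means over
    contributing pairs.  Neurons deeper than ``n_bins * bin_width_um``
    are excluded (counted); pairs where either row has zero variance
    are skipped (counted).
    """
    raster = np.atleast_2d(np.asarray(raster, dtype=float))
    depths_um = np.asarray(depths_um, dtype=float)
    in_range = (depths_um >= 0) & (depths_um < n_bins * bin_width_um)
    n_excluded = int((~in_range).sum())
    raster, depths_um = raster[in_range], depths_um[in_range]
    if raster.shape[0] < 2:
        raise DesignError("need >= 2 neurons within the binned depth range")

    bins = (depths_um // bin_width_um).astype(int)
    corr = np.corrcoef(raster)
    np.fill_diagonal(corr, np.nan)  # self-pairs excluded

    sums = np.zeros((n_bins, n_bins))
    counts = np.zeros((n_bins, n_bins), dtype=int)
    n_zero_var = 0
    iu, ju = np.triu_indices(raster.shape[0], k=1)
    for i, j in zip(iu, ju):
        r = corr[i, j]
        if np.isnan(r):
            n_zero_var += 1
            continue
        bi, bj = bins[i], bins[j]
        sums[bi, bj] += r
        counts[bi, bj] += 1
        if bi != bj:
            sums[bj, bi] += r
            counts[bj, bi] += 1
    with np.errstate(invalid="ignore"):
        matrix = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins + 1) * bin_width_um
    return BinCorrMatrix(matrix, counts, edges, slice_id, genotype, n_excluded, n_zero_var)


@dataclass
class SliceCompareResult:
    per_slice: pd.DataFrame          # slice, genotype, mean_corr, superficial_mean
    stats: pd.DataFrame              # metric, group means +/- SEM, t, p


def _mean_defined(values: np.ndarray) -> float:
    vals = values[~np.isnan(values)]
    return float(vals.mean()) if vals.size else np.nan


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0) and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def slice_group_compare(
    matrices: list[BinCorrMatrix],
    superficial_cut_um: float = 300.0,
    groups: tuple = ("WT", "HET"),
    either_neuron: bool = False,
) -> SliceCompareResult:
    """Slice-level genotype comparison of mean bin-pair correlations.

    Per slice the overall mean is taken over all defined unique bin
    pairs, and the superficial mean over matrix rows whose bin upper
    edge is at most ``superficial_cut_um`` (neuron-1 definition;
    ``either_neuron`` widens it to pairs touching a superficial bin,
    which is the same set of entries for a symmetric matrix but
    averaged over rows and columns).  A Student two-sample t across
    slices compares the genotypes on each metric.
    """
    rows = []
    for m in matrices:
        upper = m.bin_edges_um[1:]
        sup_rows = np.flatnonzero(upper <= superficial_cut_um)
        n_bins = m.matrix.shape[0]
        iu, ju = np.triu_indices(n_bins)
        overall = _mean_defined(m.matrix[iu, ju])
        if either_neuron:
            mask = np.zeros_like(m.matrix, dtype=bool)
            mask[sup_rows, :] = True
            mask[:, sup_rows] = True
            sup = _mean_defined(m.matrix[mask])
        else:
            sup = _mean_defined(m.matrix[sup_rows, :])
        rows.append({"slice": m.slice_id, "genotype": m.genotype, "mean_corr": overall, "superficial_mean": sup})
    per_slice = pd.DataFrame(rows)

    stat_rows = []
    for metric in ("mean_corr", "superficial_mean"):
        ga = per_slice.loc[per_slice["genotype"] == groups[0], metric].to_numpy()
        gb = per_slice.loc[per_slice["genotype"] == groups[1], metric].to_numpy()
        if len(ga) < 2 or len(gb) < 2:
            raise DesignError("each genotype needs >= 2 slices")
        t, p = _pooled_t(ga, gb)
        stat_rows.append(
            {
                "metric": metric,
                f"mean_{groups[0]}": ga.mean(),
                f"sem_{groups[0]}": ga.std(ddof=1) / np.sqrt(len(ga)),
                f"mean_{groups[1]}": gb.mean(),
                f"sem_{groups[1]}": gb.std(ddof=1) / np.sqrt(len(gb)),
                "t": t,
                "p": p,
            }
        )
    return SliceCompareResult(per_slice, pd.DataFrame(stat_rows))


# ---------------------------------------------------------------------------
# dendritic spine turnover
# ---------------------------------------------------------------------------

def spine_turnover(
    session1_spines: set,
    session2_spines: set,
    total_segment_length_um: float,
) -> dict:
    """Spine density and 7-day turnover percentages.

    %eliminated and %formed are relative to the spine count of the
    first session; density is spines per 10 um of dendrite on the
    first imaging day.
    """
    s1, s2 = set(session1_spines), set(session2_spines)
    if not s1:
        raise DesignError("first session has no spines")
    if total_segment_length_um <= 0:
        raise DesignError("total segment length must be positive")
    return {
        "density_per_10um": 10.0 * len(s1) / total_segment_length_um,
        "pct_formed": 100.0 * len(s2 - s1) / len(s1),
        "pct_eliminated": 100.0 * len(s1 - s2) / len(s1),
    }
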
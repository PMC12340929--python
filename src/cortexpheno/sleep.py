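"""Sleep-architecture metrics from scored hypnograms.

A hypnogram is a table of contiguous epochs (subject, genotype,
start_s, duration_s, state) covering exactly 24 h from lights-on
(ZT0).  The analysis computes per-hour state occupancy in seconds,
per-subject light (ZT0-12) and dark (ZT12-24) phase totals and the SD
of the 12 hourly values, and Welch two-sample t comparisons between
genotypes per (state, phase, metric).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError

STATES = ("Wake", "NREM", "REM")
DAY_S = 86_400
HOUR_S = 3_600


def validate_hypnogram(h: pd.DataFrame) -> pd.DataFrame:
    """Check the epoch partition: contiguous, non-overlapping, 24 h, known states."""
    required = {"start_s", "duration_s", "state"}
    missing = required - set(h.columns)
    if missing:
        raise SchemaError(f"hypnogram missing columns: {sorted(missing)}")
    h = h.sort_values("start_s").reset_index(drop=True)
    bad_states = set(h["state"]) - set(STATES)
    if bad_states:
        raise SchemaError(f"unknown states: {sorted(bad_states)}")
    starts = h["start_s"].to_numpy(dtype=float)
    durs = h["duration_s"].to_numpy(dtype=float)
    if (durs <= 0).any():
        raise SchemaError("epoch durations must be positive")
    if starts[0] != 0:
        raise SchemaError("hypnogram must start at 0 s")
    ends = starts + durs
    if not np.allclose(ends[:-1], starts[1:]):
        raise SchemaError("epochs must be contiguous without gaps or overlaps")
    if not np.isclose(ends[-1], DAY_S):
        raise SchemaError("hypnogram must cover exactly 86400 s")
    return h


def hourly_state_seconds(h: pd.DataFrame) -> pd.DataFrame:
    """24 x 3 table of seconds spent per state per hour.

    Epoch durations are apportioned to hours by exact overlap, so an
    epoch straddling an hour boundary contributes to both hours.  Row
    sums are exactly 3600.
    """
    h = validate_hypnogram(h)
    out = pd.DataFrame(0.0, index=range(24), columns=list(STATES))
    for start, dur, state in zip(h["start_s"], h["duration_s"], h["state"]):
        end = start + dur
        first, last = int(start // HOUR_S), int(np.ceil(end / HOUR_S)) - 1
        for hour in range(first, last + 1):
            lo, hi = hour * HOUR_S, (hour + 1) * HOUR_S
            out.loc[hour, state] += max(0.0, min(end, hi) - max(start, lo))
    return out


def phase_summary(hourly: pd.DataFrame) -> pd.DataFrame:
    """Light/dark totals and hourly-value SD per state.

    Totals sum hours 0-11 (light) and 12-23 (dark); SD is the sample
    (n-1) standard deviation of the 12 hourly values.  Returns one row
    per (state, phase).
    """
    if hourly.shape[0] != 24:
        raise SchemaError("need 24 complete hourly rows")
    rows = []
    for phase, hours in (("light", range(0, 12)), ("dark", range(12, 24))):
        block = hourly.loc[list(hours)]
        for state in STATES:
            vals = block[state].to_numpy(dtype=float)
            rows.append(
                {
                    "state": state,
                    "phase": phase,
                    "total_s": float(vals.sum()),
                    "sd_s": float(vals.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)


def subject_summaries(hypnograms: pd.DataFrame) -> pd.DataFrame:
    """Per-subject phase summaries for a multi-subject hypnogram table."""
    rows = []
    for (subject, genotype), grp in hypnograms.groupby(["subject", "genotype"]):
        summ = phase_summary(hourly_state_seconds(grp))
        summ.insert(0, "subject", subject)
        summ.insert(1, "genotype", genotype)
        rows.append(summ)
    return pd.concat(rows, ignore_index=True)


def welch_compare(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t, Welch-Satterthwaite df, and two-sided p for two samples.

    Falls back to the pooled df with a warning-friendly (t=0, p=1)
    convention when both groups are constant.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return 0.0, float(n1 + n2 - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def genotype_compare(
    summaries: pd.DataFrame,
    groups: tuple = ("WT", "HET"),
) -> pd.DataFrame:
    """Welch comparisons of phase totals and SDs between genotypes.

    One row per (state, phase, metric) with group means +/- SEM, t,
    Welch df, and two-sided p.  No multiple-testing correction is
    applied; the twelve raw p-values are reported side by side.
    """
    rows = []
    for metric in ("total_s", "sd_s"):
        for (state, phase), grp in summaries.groupby(["state", "phase"]):
            a = grp.loc[grp["genotype"] == groups[0], metric].to_numpy()
            b = grp.loc[grp["genotype"] == groups[1], metric].to_numpy()
            if len(a) < 2 or len(b) < 2:
                raise SchemaError("each genotype needs >= 2 subjects")
            t, df, p = welch_compare(b, a)  # test group relative to reference
            rows.append(
                {
                    "state": state,
                    "phase": phase,
                    "metric": metric,
                    f"mean_{groups[0]}": a.mean(),
                    f"sem_{groups[0]}": a.std(ddof=1) / np.sqrt(len(a)),
                    f"mean_{groups[1]}": b.mean(),
                    f"sem_{groups[1]}": b.std(ddof=1) / np.sqrt(len(b)),
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
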
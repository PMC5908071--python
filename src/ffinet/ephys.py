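"""Stimulus-locked analysis of extracellular recordings.

Implements the analysis applied to paired visual/optogenetic
experiments in awake mouse V1: spike counts in a 175-ms response
window (starting 25 ms after stimulus onset) with a matched 175-ms
baseline window ending at onset; per-unit nonlinearity classification
by a two-sample two-tailed KS test on baseline-subtracted response
counts with and without optogenetic light (p < 0.01); shank- and
unit-level response filters at 0.2 spk/s; ranking of shanks by mean
ChR2-induced baseline shift into three groups; and LOWESS summaries
with bootstrapped confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["RecordingDataset", "UnitScaling", "visual_response_counts",
           "classify_nonlinearity", "unit_filters", "group_by_chr2_effect",
           "smoothed_summary", "psth", "analyze_dataset",
           "RESPONSE_WINDOW_S", "RESPONSE_OFFSET_S", "ALPHA"]

RESPONSE_WINDOW_S = 0.175   # length of both counting windows
RESPONSE_OFFSET_S = 0.025   # response window starts this long after onset
ALPHA = 0.01                # KS significance threshold
RESPONSE_THRESHOLD = 0.2    # spk/s, shank and unit inclusion


@dataclass
class RecordingDataset:
    """Spike table + stimulus/light event table + unit metadata.

    ``spikes``: columns (unit_id, time_s).  ``events``: columns
    (onset_s, contrast_pct, light_on).  ``units``: columns (unit_id,
    shank, depth_um, su_flag).
    """

    spikes: pd.DataFrame
    events: pd.DataFrame
    units: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df, cols in ((self.spikes, {"unit_id", "time_s"}),
                         (self.events, {"onset_s", "contrast_pct",
                                        "light_on"}),
                         (self.units, {"unit_id", "shank"})):
            missing = cols - set(df.columns)
            if missing:
                raise ValueError(f"missing columns: {sorted(missing)}")
        if len(self.events):
            c = self.events["contrast_pct"]
            if (c <= 0).any() or (c > 100).any():
                raise ValueError("contrasts must lie in (0, 100]")
            if (self.events["onset_s"] < RESPONSE_WINDOW_S).any():
                raise ValueError("analysis window precedes recording start")

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(d / "spikes.csv", index=False)
        self.events.to_csv(d / "events.csv", index=False)
        self.units.to_csv(d / "units.csv", index=False)

    @classmethod
    def load(cls, directory) -> "RecordingDataset":
        d = Path(directory)
        return cls(spikes=pd.read_csv(d / "spikes.csv"),
                   events=pd.read_csv(d / "events.csv"),
                   units=pd.read_csv(d / "units.csv"))


@dataclass
class UnitScaling:
    """Per-unit summary of response scaling under optogenetic light."""

    unit_id: int
    baseline_off: float
    baseline_on: float
    response_off: float   # baseline-subtracted, spk/s
    response_on: float
    response_diff: float  # on - off
    sem_diff: float
    p_value: float
    label: str            # linear / supralinear / sublinear


def _counts_in(spike_times: np.ndarray, starts: np.ndarray,
               length: float) -> np.ndarray:
    lo = np.searchsorted(spike_times, starts)
    hi = np.searchsorted(spike_times, starts + length)
    return (hi - lo).astype(int)


def visual_response_counts(ds: RecordingDataset, unit_id: int,
                           condition: str = "light-off",
                           contrast: float | None = None) -> tuple:
    """Per-presentation (baseline, response) spike counts for a unit.

    The response window is [onset+25 ms, onset+200 ms) and the baseline
    window [onset-175 ms, onset); both are 175 ms.  Raises if windows
    of successive events overlap (protocol violation).
    """
    if condition not in ("light-off", "light-on"):
        raise ValueError("condition must be 'light-off' or 'light-on'")
    ev = ds.events[ds.events["light_on"] == (condition == "light-on")]
    if contrast is not None:
        ev = ev[ev["contrast_pct"] == contrast]
    onsets = np.sort(ev["onset_s"].to_numpy())
    span = RESPONSE_OFFSET_S + RESPONSE_WINDOW_S  # window extent after onset
    if len(onsets) > 1 and np.any(np.diff(onsets) < span + RESPONSE_WINDOW_S):
        raise ValueError("analysis windows of successive events overlap")
    st = np.sort(ds.spikes.loc[ds.spikes["unit_id"] == unit_id,
                               "time_s"].to_numpy())
    baseline = _counts_in(st, onsets - RESPONSE_WINDOW_S, RESPONSE_WINDOW_S)
    response = _counts_in(st, onsets + RESPONSE_OFFSET_S, RESPONSE_WINDOW_S)
    return baseline, response


def classify_nonlinearity(counts_off: tuple, counts_on: tuple,
                          alpha: float = ALPHA) -> dict:
    """Two-sample two-tailed KS test on baseline-subtracted counts.

    ``counts_off``/``counts_on`` are (baseline, response) count pairs
    per light condition.  A unit is significantly nonlinear when the KS
    p-value is below ``alpha``; the sign of the mean difference of the
    baseline-subtracted response counts decides supra- vs sublinear.
    The exact KS null distribution is used for fewer than 30
    presentations per condition.
    """
    b_off, r_off = (np.asarray(a) for a in counts_off)
    b_on, r_on = (np.asarray(a) for a in counts_on)
    if len(r_off) < 2 or len(r_on) < 2:
        raise ValueError("need at least 2 presentations per condition")
    d_off = r_off - b_off
    d_on = r_on - b_on
    method = "exact" if min(len(d_off), len(d_on)) < 30 else "auto"
    ks = stats.ks_2samp(d_off, d_on, alternative="two-sided",
                        method=method)
    diff = d_on.mean() - d_off.mean()
    if ks.pvalue < alpha:
        label = "supralinear" if diff > 0 else "sublinear"
    else:
        label = "linear"
    w = RESPONSE_WINDOW_S
    n_off, n_on = len(d_off), len(d_on)
    sem = np.sqrt(d_on.var(ddof=1) / n_on + d_off.var(ddof=1) / n_off) / w
    return {"p_value": float(ks.pvalue), "label": label,
            "baseline_off": b_off.mean() / w, "baseline_on": b_on.mean() / w,
            "response_off": d_off.mean() / w, "response_on": d_on.mean() / w,
            "response_diff": diff / w, "sem_diff": float(sem)}


def nonlinear_fraction(labels) -> float:
    """Percentage of units classified as nonlinear (supra or sub)."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("no units")
    return 100.0 * float(np.mean(labels != "linear"))


def unit_filters(ds: RecordingDataset,
                 threshold: float = RESPONSE_THRESHOLD) -> pd.DataFrame:
    """Shank-level then unit-level visual-response inclusion filters.

    A shank is kept when its units' mean light-off visual response
    (baseline-subtracted) exceeds ``threshold`` spk/s; within kept
    shanks, units must individually exceed the same threshold.
    Returns a frame with per-unit responses, exclusion reasons and an
    ``included`` flag.
    """
    rows = []
    for uid in ds.units["unit_id"]:
        b, r = visual_response_counts(ds, uid, "light-off")
        resp = (r.mean() - b.mean()) / RESPONSE_WINDOW_S if len(r) else 0.0
        rows.append({"unit_id": uid, "response_off": resp})
    out = pd.DataFrame(rows).merge(ds.units, on="unit_id")
    shank_mean = out.groupby("shank")["response_off"].mean()
    good_shanks = set(shank_mean[shank_mean > threshold].index)
    reasons = []
    for _, row in out.iterrows():
        if row["shank"] not in good_shanks:
            reasons.append("shank-below-threshold")
        elif row["response_off"] <= threshold:
            reasons.append("unit-below-threshold")
        else:
            reasons.append("")
    out["exclusion_reason"] = reasons
    out["included"] = out["exclusion_reason"] == ""
    return out


def group_by_chr2_effect(ds: RecordingDataset, shifts: pd.DataFrame,
                         n_groups: int = 3) -> pd.DataFrame:
    """Rank shanks by mean ChR2 baseline shift; split into groups.

    ``shifts`` carries per-unit baseline shifts (column
    ``baseline_shift``, light-on minus light-off) and ``unit_id``.
    Shanks are ranked by their units' mean shift and divided into
    ``n_groups`` contiguous thirds (ties broken by shank id), so the
    unit counts per group may differ slightly.
    """
    merged = shifts.merge(ds.units[["unit_id", "shank"]], on="unit_id")
    shank_mean = (merged.groupby("shank")["baseline_shift"].mean()
                  .reset_index())
    if len(shank_mean) < n_groups:
        raise ValueError("fewer shanks than groups")
    shank_mean = shank_mean.sort_values(["baseline_shift", "shank"],
                                        kind="stable").reset_index(drop=True)
    bounds = np.array_split(np.arange(len(shank_mean)), n_groups)
    shank_group = {}
    for g, idx in enumerate(bounds):
        for k in idx:
            shank_group[shank_mean.loc[k, "shank"]] = g
    merged["group"] = merged["shank"].map(shank_group)
    return merged


def smoothed_summary(x: np.ndarray, y: np.ndarray, *, frac: float = 0.6,
                     n_boot: int = 1000, seed: int = 0,
                     grid: np.ndarray | None = None) -> pd.DataFrame:
    """LOWESS curve of y on x with a bootstrapped 95% CI over units."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 units")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x values (all equal)")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    fit = lowess(y, x, frac=frac, xvals=grid)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(grid)))
    n = len(x)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = lowess(y[idx], x[idx], frac=frac, xvals=grid)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return pd.DataFrame({"x": grid, "fit": fit, "ci_lo": lo, "ci_hi": hi})


def psth(ds: RecordingDataset, unit_id: int, *, bin_ms: float = 10.0,
         window: tuple = (-0.3, 0.7), frac: float = 0.25,
         condition: str | None = None) -> pd.DataFrame:
    """Stimulus-aligned firing-rate trace, LOWESS-smoothed.

    Spikes are binned around each stimulus onset, averaged over
    presentations, and smoothed.  The smoothed trace conserves the
    total spike count of the raw histogram up to smoothing tolerance.
    """
    ev = ds.events
    if condition is not None:
        ev = ev[ev["light_on"] == (condition == "light-on")]
    onsets = ev["onset_s"].to_numpy()
    st = np.sort(ds.spikes.loc[ds.spikes["unit_id"] == unit_id,
                               "time_s"].to_numpy())
    edges = np.arange(window[0], window[1] + 1e-9, bin_ms * 1e-3)
    acc = np.zeros(len(edges) - 1)
    for t0 in onsets:
        c, _ = np.histogram(st - t0, bins=edges)
        acc += c
    rate = acc / (max(len(onsets), 1) * bin_ms * 1e-3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # no robustness iterations: they would treat sharp transients
    # (single-bin bumps) as outliers and flatten them
    smooth = lowess(rate, centers, frac=frac, it=0, xvals=centers)
    return pd.DataFrame({"time_s": centers, "rate": rate,
                         "rate_smooth": smooth})


def analyze_dataset(ds: RecordingDataset, *, alpha: float = ALPHA,
                    apply_filters: bool = True,
                    contrast: float | None = None) -> pd.DataFrame:
    """Full per-unit scaling analysis of a recording.

    Applies the inclusion filters, computes per-unit baseline rates and
    baseline-subtracted responses in both light conditions, classifies
    nonlinearity, and attaches shank groups ranked by ChR2 effect.
    """
    filt = unit_filters(ds)
    keep = filt[filt["included"]]["unit_id"] if apply_filters \
        else ds.units["unit_id"]
    rows = []
    for uid in keep:
        off = visual_response_counts(ds, uid, "light-off", contrast)
        on = visual_response_counts(ds, uid, "light-on", contrast)
        if len(off[0]) < 2 or len(on[0]) < 2:
            continue
        res = classify_nonlinearity(off, on, alpha)
        res["unit_id"] = uid
        res["baseline_shift"] = res["baseline_on"] - res["baseline_off"]
        rows.append(res)
    table = pd.DataFrame(rows)
    if len(table) and ds.units["shank"].nunique() >= 3:
        grouped = group_by_chr2_effect(ds, table[["unit_id",
                                                  "baseline_shift"]])
        table = table.merge(grouped[["unit_id", "group"]], on="unit_id")
    return table
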
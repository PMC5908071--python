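"""Synthetic recordings with the paired visual/optogenetic protocol.

Generates spike-time tables with known ground truth so the analysis
pipeline can be validated end to end: visual stimuli every 1 s in sets
of 10, optogenetic light on alternating sets (onset 500 ms before the
first stimulus of a set, total pulse 10.2 s), a 1-s delay after each
set, heterogeneous per-unit baseline rates, stimulus-evoked transients
and ChR2 baseline shifts, and a per-unit additivity coefficient c
(response under light = c x response without light; c = 1 is perfectly
additive).

Also provides down-scaled fixture networks for fast simulator tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ephys import RecordingDataset
from .network import NetworkSpec

__all__ = ["ProtocolSpec", "SyntheticUnitSpec", "generate_events",
           "generate_unit_spikes", "generate_dataset",
           "mouse_v1_population", "fixture_network"]


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing constants of the stimulation protocol."""

    isi_s: float = 1.0             # inter-stimulus onset interval
    stimuli_per_set: int = 10
    light_lead_s: float = 0.5      # light onset before first stimulus
    light_lag_s: float = 0.5       # light offset after end of last stimulus
    stimulus_dur_s: float = 0.2    # nominal stimulus extent (onset->end)
    stimulus_fwhm_ms: float = 115.0
    inter_set_delay_s: float = 1.0
    contrasts: tuple = (8.0, 90.0)

    @property
    def light_duration_s(self) -> float:
        """Total light pulse duration implied by the timing constants.

        lead + (n-1) ISIs to the last onset + stimulus extent + lag;
        10.2 s with the defaults.
        """
        return (self.light_lead_s + (self.stimuli_per_set - 1) * self.isi_s
                + self.stimulus_dur_s + self.light_lag_s)

    @property
    def set_period_s(self) -> float:
        return self.light_duration_s + self.inter_set_delay_s


@dataclass(frozen=True)
class SyntheticUnitSpec:
    """Ground-truth firing model of one synthetic unit.

    Instantaneous rate = baseline + (light ? chr2_shift : 0)
    + response_amp x contrast_scale(contrast) x kernel(t - onset)
    x (additivity if light else 1); Poisson spiking.
    """

    unit_id: int
    shank: int
    baseline: float = 5.0          # spk/s
    response_amp: float = 10.0     # peak evoked rate at full contrast
    chr2_shift: float = 5.0        # baseline change under light, spk/s
    additivity: float = 1.0        # c; 1 = linear summation
    c50: float = 20.0              # semi-saturation contrast (%)
    depth_um: float = 300.0
    su_flag: bool = True

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.response_amp < 0:
            raise ValueError("rates must be >= 0")
        if self.additivity < 0:
            raise ValueError("additivity coefficient must be >= 0")

    def contrast_scale(self, contrast_pct: float) -> float:
        """Saturating (Naka-Rushton) contrast-response scale in [0,1]."""
        c = contrast_pct
        return c**2 / (c**2 + self.c50**2)


def generate_events(protocol: ProtocolSpec, n_sets: int,
                    seed: int = 0) -> pd.DataFrame:
    """Event table for alternating light-off / light-on stimulus sets.

    Within a set, stimulus onsets are exactly ``isi_s`` apart.  Light
    pulses accompany every second set, starting ``light_lead_s`` before
    the first onset and spanning ``light_duration_s``.  Contrasts are
    drawn per presentation from ``protocol.contrasts``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    t = 1.0  # lead-in so baseline windows exist for the first stimulus
    for s in range(n_sets):
        light = s % 2 == 1
        light_on_t = t
        first_onset = t + protocol.light_lead_s
        for k in range(protocol.stimuli_per_set):
            rows.append({
                "onset_s": first_onset + k * protocol.isi_s,
                "contrast_pct": float(rng.choice(protocol.contrasts)),
                "light_on": light,
                "set_index": s,
                "light_onset_s": light_on_t if light else np.nan,
                "light_offset_s": (light_on_t + protocol.light_duration_s
                                   if light else np.nan),
            })
        t = light_on_t + protocol.light_duration_s \
            + protocol.inter_set_delay_s
    return pd.DataFrame(rows)


def _rate_profile(spec: SyntheticUnitSpec, events: pd.DataFrame,
                  t_end: float, bin_s: float = 0.001):
    """Piecewise rate on a fine grid, plus clip bookkeeping."""
    n = int(np.ceil(t_end / bin_s))
    tt = (np.arange(n) + 0.5) * bin_s
    rate = np.full(n, spec.baseline)
    light = events[events["light_on"]]
    for t0, t1 in set(zip(light["light_onset_s"], light["light_offset_s"])):
        i0 = int(t0 / bin_s)
        i1 = min(int(t1 / bin_s), n)
        if i0 < i1:
            rate[i0:i1] += spec.chr2_shift
    # raised-cosine response kernel; FWHM 115 ms = half the support
    half_width = 0.115
    for _, ev in events.iterrows():
        onset = ev["onset_s"]
        amp = spec.response_amp * spec.contrast_scale(ev["contrast_pct"])
        if ev["light_on"]:
            amp *= spec.additivity
        sel = (tt >= onset) & (tt < onset + 2 * half_width)
        phase = (tt[sel] - onset) / (2 * half_width)
        rate[sel] += amp * 0.5 * (1 - np.cos(2 * np.pi * phase))
    clipped = rate < 0
    rate[clipped] = 0.0
    return tt, rate, bool(clipped.any())


def generate_unit_spikes(spec: SyntheticUnitSpec, events: pd.DataFrame,
                         seed: int = 0, t_end: float | None = None):
    """Inhomogeneous-Poisson spike times for one unit.

    Returns (spike_times, info) where info records whether the rate
    was clipped at zero and the expected counts in the analysis
    windows (ground truth for oracle tests).
    """
    if t_end is None:
        t_end = float(events["onset_s"].max()) + 2.0 if len(events) else 1.0
    rng = np.random.default_rng(seed)
    bin_s = 0.001
    tt, rate, clipped = _rate_profile(spec, events, t_end, bin_s)
    counts = rng.poisson(rate * bin_s)
    idx = np.nonzero(counts)[0]
    times = np.concatenate([
        tt[i] - bin_s / 2 + rng.uniform(0, bin_s, size=counts[i])
        for i in idx]) if len(idx) else np.empty(0)
    times.sort()
    # ground-truth expected window counts per presentation
    from .ephys import RESPONSE_OFFSET_S, RESPONSE_WINDOW_S
    exp = []
    for _, ev in events.iterrows():
        onset = ev["onset_s"]
        sel_b = (tt >= onset - RESPONSE_WINDOW_S) & (tt < onset)
        sel_r = (tt >= onset + RESPONSE_OFFSET_S) & \
                (tt < onset + RESPONSE_OFFSET_S + RESPONSE_WINDOW_S)
        exp.append({"onset_s": onset, "light_on": bool(ev["light_on"]),
                    "expected_baseline": rate[sel_b].sum() * bin_s,
                    "expected_response": rate[sel_r].sum() * bin_s})
    return times, {"clipped": clipped,
                   "expected_counts": pd.DataFrame(exp)}


def mouse_v1_population(n_units: int = 60, n_shanks: int = 6, *,
                        mean_baseline: float = 5.8,
                        mean_response: float = 9.6,
                        mean_shift: float = 5.0,
                        additivity: float | np.ndarray = 1.0,
                        graded_shift_by_shank: bool = False,
                        seed: int = 0) -> list:
    """Heterogeneous unit population with V1-like summary statistics.

    Baselines and response amplitudes are lognormal with the given
    means; ChR2 shifts are positive and scale with the shank's position
    when ``graded_shift_by_shank`` (emulating the fall-off of opsin
    expression with distance from the injection site).  ``additivity``
    may be a scalar applied to every unit or an array of length
    ``n_units``.
    """
    rng = np.random.default_rng(seed)
    add = np.broadcast_to(np.asarray(additivity, dtype=float),
                          (n_units,))
    units = []
    for u in range(n_units):
        shank = u % n_shanks
        shift = mean_shift * rng.lognormal(-0.125, 0.5)
        if graded_shift_by_shank:
            shift *= (shank + 1) / ((n_shanks + 1) / 2)
        units.append(SyntheticUnitSpec(
            unit_id=u, shank=shank,
            baseline=mean_baseline * rng.lognormal(-0.18, 0.6),
            response_amp=2.0 * mean_response * rng.lognormal(-0.125, 0.5),
            chr2_shift=shift, additivity=float(add[u]),
            depth_um=float(rng.uniform(100, 700)),
            su_flag=bool(rng.random() < 0.5)))
    return units


def generate_dataset(units: list, protocol: ProtocolSpec = ProtocolSpec(),
                     n_sets: int = 10, seed: int = 0) -> tuple:
    """Full synthetic recording plus a ground-truth sidecar table."""
    events = generate_events(protocol, n_sets, seed=seed)
    t_end = float(events["onset_s"].max()) + 2.0
    spike_rows = []
    truth_rows = []
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(units))
    for spec, s in zip(units, child):
        times, info = generate_unit_spikes(
            spec, events, seed=int(s.generate_state(1)[0] % (2**31)),
            t_end=t_end)
        spike_rows.append(pd.DataFrame({"unit_id": spec.unit_id,
                                        "time_s": times}))
        truth_rows.append({
            "unit_id": spec.unit_id, "shank": spec.shank,
            "baseline": spec.baseline, "response_amp": spec.response_amp,
            "chr2_shift": spec.chr2_shift, "additivity": spec.additivity,
            "clipped": info["clipped"]})
    spikes = pd.concat(spike_rows, ignore_index=True)
    unit_meta = pd.DataFrame([{
        "unit_id": u.unit_id, "shank": u.shank, "depth_um": u.depth_um,
        "su_flag": u.su_flag} for u in units])
    ds = RecordingDataset(spikes=spikes,
                          events=events.drop(columns=["set_index"]),
                          units=unit_meta,
                          meta={"seed": seed, "n_sets": n_sets})
    return ds, pd.DataFrame(truth_rows)


def fixture_network(scale: float = 0.2,
                    base: NetworkSpec | None = None,
                    max_sparsity: float = 0.5) -> NetworkSpec:
    """Down-scaled network preserving expected in-degree x weight.

    Populations shrink by ``scale``; sparsity grows by 1/scale so each
    cell keeps its expected number (and weight) of inputs.  If the
    required sparsity would exceed ``max_sparsity`` it is capped and
    the weights are scaled up to preserve the in-degree x weight
    product instead.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    base = base or NetworkSpec()
    if scale == 1.0:
        return base
    p = base.sparsity / scale
    w_mult = 1.0
    if p > max_sparsity:
        w_mult = p / max_sparsity
        p = max_sparsity
    n_e = int(round(base.n_e * scale))
    n_i = int(round(base.n_i * scale))
    if n_e < 1 or n_i < 1 or p <= 0:
        raise ValueError("scale too small for a valid network")
    return replace(base, n_e=n_e, n_i=n_i, sparsity=p,
                   w_e=base.w_e * w_mult, w_i=base.w_i * w_mult)
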
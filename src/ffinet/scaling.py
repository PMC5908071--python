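"""Response-scaling measurements and parameter sweeps.

The central measurement: drive the network with a staircase of
feedforward input (rates multiplied by 1, 2, 3, 4 in successive 1-s
steps), record the mean E rate at each step, and ask whether the
*increment* per step stays constant (linear/additive summation),
shrinks (sublinear) or grows (supralinear).  Grids over feedforward
rates or local-connectivity strengths colour each cell by the percent
change of the second increment relative to the first, masking cells
whose first response falls outside the 5-20 spk/s analysis band or
whose dynamics are unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import (Background, base_program, calibrate_spontaneous,
                        find_input_for_response)
from .network import Connectivity, ExtraSet, NetworkSpec, build_connectivity
from .simulate import (REFRACTORY_CEILING, mean_population_rate,
                       per_neuron_rates, simulate, unstable_time)
from .stimulus import (Chr2Drive, PoissonDrive, StimulusProgram,
                       choose_targets, staircase_segments)

__all__ = ["ScalingCurve", "SweepGrid", "percent_change_response",
           "scaling_curve", "sweep_feedforward", "sweep_local_connectivity",
           "sweep_sparsity_strength", "split_scaling_by_drive",
           "conductance_plus_visual", "combined_protocol_calibration",
           "MASK_OK", "MASK_LOW", "MASK_HIGH",
           "MASK_UNSTABLE"]

MASK_OK = "ok"
MASK_LOW = "rate<5"
MASK_HIGH = "rate>20"
MASK_UNSTABLE = "unstable"

# Analysis band for first responses (spk/s); responses above
# HIGH_RATE_FLAG are refractory-confounded and flagged on curves.
RESPONSE_BAND = (5.0, 20.0)
HIGH_RATE_FLAG = 50.0


def percent_change_response(r1: float, r2: float) -> float:
    """Percent change of the second response relative to the first.

    ``r1`` and ``r2`` are baseline-referenced response increments
    (spk/s).  0 means exactly linear summation; negative values mean
    the second response was smaller (sublinear).
    """
    if not np.isfinite(r1) or r1 <= 0:
        raise ValueError("first response must be positive")
    return 100.0 * (r2 - r1) / r1


@dataclass
class ScalingCurve:
    """Step responses of one staircase run.

    ``prior``/``response`` are absolute mean E rates before and during
    each step; ``delta`` their difference (the per-step increment).
    ``high_rate`` flags steps whose prior rate exceeds 50 spk/s;
    ``truncated`` is set when instability cut the staircase short.
    """

    multipliers: list
    prior: np.ndarray
    response: np.ndarray
    delta: np.ndarray
    spontaneous: float
    high_rate: np.ndarray
    truncated: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def percent_change(self) -> float:
        """Percent change of the 2nd increment vs the 1st."""
        if len(self.delta) < 2:
            return float("nan")
        return percent_change_response(self.delta[0], self.delta[1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "multiplier": self.multipliers[: len(self.response)],
            "prior_rate": self.prior,
            "response_rate": self.response,
            "delta": self.delta,
            "high_rate": self.high_rate,
        })


def scaling_curve(conn: Connectivity, ff_e_rate: float,
                  ff_i_rate: float = 0.0, *,
                  multipliers=(1, 2, 3, 4),
                  bg: Background = Background(),
                  aux: tuple = (None, 0.0),
                  target_fraction: float = 0.33,
                  step_s: float = 1.0, settle_s: float = 1.0,
                  measure_s: float = 0.5, seed: int = 0,
                  chr2=None, ff_weight: float | None = None) -> ScalingCurve:
    """Run a feedforward staircase and measure per-step increments.

    The E (and optionally I) feedforward rates are stepped through
    ``rate * m`` for each multiplier, 1 s per step; the mean E rate over
    the last ``measure_s`` of each step is the step response.  The run
    is truncated with a flag if the population rate saturates.
    """
    multipliers = list(multipliers)
    w_ff = conn.spec.w_e if ff_weight is None else ff_weight
    prog = base_program(conn, bg, aux[0], aux[1])
    tg_e = choose_targets(conn.e_ids, target_fraction,
                          seed=conn.spec.seed + 101)
    prog.poisson.append(PoissonDrive(
        tg_e, staircase_segments(settle_s, step_s, ff_e_rate, multipliers),
        w_ff))
    if ff_i_rate > 0:
        tg_i = choose_targets(conn.i_ids, target_fraction,
                              seed=conn.spec.seed + 202)
        prog.poisson.append(PoissonDrive(
            tg_i, staircase_segments(settle_s, step_s, ff_i_rate,
                                     multipliers), w_ff))
    if chr2 is not None:
        prog.chr2.append(chr2)
    duration = settle_s + step_s * len(multipliers)
    rec = simulate(conn, prog, duration_s=duration, seed=seed,
                   raise_on_blowup=False)
    bad_t = unstable_time(rec, conn.e_ids,
                          t_refrac_ms=conn.params.t_refrac_ms)

    spont = mean_population_rate(
        rec, conn.e_ids, (max(0.0, settle_s - measure_s), settle_s))
    prior, resp = [], []
    truncated = False
    prev = spont
    for k in range(len(multipliers)):
        t1 = settle_s + (k + 1) * step_s
        if bad_t is not None and bad_t < t1:
            truncated = True
            break
        r = mean_population_rate(rec, conn.e_ids, (t1 - measure_s, t1))
        prior.append(prev)
        resp.append(r)
        prev = r
    prior = np.asarray(prior)
    resp = np.asarray(resp)
    return ScalingCurve(
        multipliers=multipliers, prior=prior, response=resp,
        delta=resp - prior, spontaneous=spont,
        high_rate=prior > HIGH_RATE_FLAG, truncated=truncated,
        meta={"ff_e_rate": ff_e_rate, "ff_i_rate": ff_i_rate, "seed": seed})


@dataclass
class SweepGrid:
    """2-D sweep result: first responses, percent changes and masks."""

    x_name: str
    x_values: np.ndarray
    y_name: str
    y_values: np.ndarray
    first_response: np.ndarray  # shape (len(y), len(x))
    percent_change: np.ndarray  # NaN where masked
    mask: np.ndarray            # object array of mask labels

    def __post_init__(self) -> None:
        shape = (len(self.y_values), len(self.x_values))
        for a in (self.first_response, self.percent_change, self.mask):
            if a.shape != shape:
                raise ValueError("grid arrays must match axis lengths")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, y in enumerate(self.y_values):
            for i, x in enumerate(self.x_values):
                rows.append({self.x_name: x, self.y_name: y,
                             "first_response": self.first_response[j, i],
                             "percent_change": self.percent_change[j, i],
                             "mask": self.mask[j, i]})
        return pd.DataFrame(rows)


def _grid_cell(curve: ScalingCurve) -> tuple[float, float, str]:
    """(first response, percent change, mask label) for one grid cell."""
    if curve.truncated or len(curve.delta) < 2:
        return float("nan"), float("nan"), MASK_UNSTABLE
    first = float(curve.response[0])
    if first < RESPONSE_BAND[0]:
        return first, float("nan"), MASK_LOW
    if first > RESPONSE_BAND[1]:
        return first, float("nan"), MASK_HIGH
    if curve.delta[0] <= 0:
        return first, float("nan"), MASK_LOW
    return first, float(curve.percent_change), MASK_OK


def sweep_feedforward(conn: Connectivity, e_rates, i_rates, *,
                      multiplier: int = 2,
                      bg: Background = Background(),
                      aux: tuple = (None, 0.0),
                      target_fraction: float = 0.33,
                      seed: int = 0, **curve_kw) -> SweepGrid:
    """Grid of response scaling over feedforward E and I rates.

    Each cell runs a two-step staircase (multipliers 1 and
    ``multiplier``); colour value is the percent change of the second
    increment, contour value the first response, with the 5-20 spk/s
    band and instability masks applied.
    """
    e_rates = np.asarray(e_rates, dtype=float)
    i_rates = np.asarray(i_rates, dtype=float)
    shape = (len(i_rates), len(e_rates))
    first = np.full(shape, np.nan)
    pct = np.full(shape, np.nan)
    mask = np.empty(shape, dtype=object)
    for j, ri in enumerate(i_rates):
        for i, re_ in enumerate(e_rates):
            curve = scaling_curve(conn, re_, ri,
                                  multipliers=(1, multiplier), bg=bg,
                                  aux=aux, target_fraction=target_fraction,
                                  seed=seed, **curve_kw)
            first[j, i], pct[j, i], mask[j, i] = _grid_cell(curve)
    return SweepGrid("ff_e_rate", e_rates, "ff_i_rate", i_rates,
                     first, pct, mask)


def sweep_local_connectivity(spec: NetworkSpec, e2i_fracs, i2i_fracs, *,
                             ff_mode: str = "e-only",
                             ff_e_rate: float, ff_i_rate: float = 0.0,
                             multiplier: int = 2,
                             bg: Background = Background(),
                             aux: tuple = (None, 0.0),
                             recalibrate: bool = False,
                             spont_target: float = 5.0,
                             spont_tol: float = 1.0,
                             seed: int = 0, **curve_kw) -> SweepGrid:
    """Scaling grid over extra E->I and I->I connection strengths.

    Axis values are fractions of the balancing-set input (extra-set
    in-degree x weight over balancing in-degree x weight, e.g. 0.2 for
    a 20% increase in the total input a cell receives from that
    population).  For each cell the extra sets are installed and a
    two-step staircase at fixed feedforward rates is run.  By default
    the auxiliary input ``aux`` (calibrated once on the balanced
    network) and the feedforward rates are held constant across the
    whole grid; with ``recalibrate=True`` the spontaneous rate is
    re-tuned per cell instead and cells whose recalibration fails are
    masked unstable.  First responses outside the 5-20 spk/s band are
    masked either way.
    """
    e2i_fracs = np.asarray(e2i_fracs, dtype=float)
    i2i_fracs = np.asarray(i2i_fracs, dtype=float)
    shape = (len(i2i_fracs), len(e2i_fracs))
    first = np.full(shape, np.nan)
    pct = np.full(shape, np.nan)
    mask = np.empty(shape, dtype=object)
    for j, fi in enumerate(i2i_fracs):
        for i, fe in enumerate(e2i_fracs):
            extra = []
            if fe > 0:
                extra.append(ExtraSet("e", "i", spec.sparsity,
                                      fe * spec.w_e))
            if fi > 0:
                extra.append(ExtraSet("i", "i", spec.sparsity,
                                      fi * spec.w_i))
            conn = build_connectivity(spec.with_extra(*extra))
            cell_aux = aux
            if recalibrate:
                cal = calibrate_spontaneous(conn, spont_target, spont_tol,
                                            bg=bg, seed=seed,
                                            discard_s=0.5, measure_s=2.0,
                                            max_iter=8)
                if not cal.converged:
                    mask[j, i] = MASK_UNSTABLE
                    continue
                cell_aux = (cal.extra.get("aux_pop"), cal.value)
            curve = scaling_curve(conn, ff_e_rate,
                                  ff_i_rate if ff_mode == "e-and-i" else 0.0,
                                  multipliers=(1, multiplier), bg=bg,
                                  aux=cell_aux, seed=seed, **curve_kw)
            first[j, i], pct[j, i], mask[j, i] = _grid_cell(curve)
    return SweepGrid("e2i_extra_frac", e2i_fracs, "i2i_extra_frac",
                     i2i_fracs, first, pct, mask)


def sweep_sparsity_strength(base_spec: NetworkSpec, rows, *,
                            bg: Background = Background(),
                            target_response: float = 15.0,
                            response_tol: float = 1.5,
                            multipliers=(1, 2, 3, 4),
                            seed: int = 0,
                            spont_target: float = 5.0,
                            spont_tol: float = 0.75,
                            **curve_kw) -> list:
    """Paired E-only / E+I scaling curves for (sparsity, strength) rows.

    ``rows`` is a list of (sparsity, strength_factor) pairs; the
    strength factor multiplies both recurrent weights.  Each row is
    recalibrated: spontaneous rate to 5 spk/s, then the feedforward E
    rate giving a 15 spk/s response, then the feedforward-inhibition
    rate that restores a 15 spk/s response when the E rate is tripled.
    Returns a list of row dicts with the two curves; rows whose
    calibration fails are flagged, not fabricated.
    """
    out = []
    for sparsity, strength in rows:
        spec = NetworkSpec(
            n_e=base_spec.n_e, n_i=base_spec.n_i, sparsity=sparsity,
            w_e=base_spec.w_e * strength, w_i=base_spec.w_i * strength,
            extra_sets=base_spec.extra_sets, seed=base_spec.seed)
        conn = build_connectivity(spec)
        row = {"sparsity": sparsity, "strength": strength,
               "stable": False, "flag": None}
        cal = calibrate_spontaneous(conn, spont_target, spont_tol, bg=bg,
                                    seed=seed, discard_s=0.5,
                                    measure_s=2.0, max_iter=8)
        if not cal.converged:
            row["flag"] = "spontaneous-calibration-failed"
            out.append(row)
            continue
        aux = (cal.extra.get("aux_pop"), cal.value)
        cal_e = find_input_for_response(conn, target_response,
                                        response_tol, ff_mode="e-only",
                                        bg=bg, aux=aux, seed=seed)
        if not cal_e.converged:
            row["flag"] = "e-input-calibration-failed"
            out.append(row)
            continue
        r_e = cal_e.value
        cal_i = find_input_for_response(conn, target_response,
                                        response_tol,
                                        ff_mode="i-given-e",
                                        fixed_e_rate=3.0 * r_e, bg=bg,
                                        aux=aux, seed=seed)
        if not cal_i.converged:
            row["flag"] = "i-input-calibration-failed"
            out.append(row)
            continue
        row["ff_e_rate"] = r_e
        row["ff_i_rate"] = cal_i.value
        row["aux"] = aux
        row["curve_e_only"] = scaling_curve(
            conn, r_e, 0.0, multipliers=multipliers, bg=bg, aux=aux,
            seed=seed, **curve_kw)
        row["curve_e_and_i"] = scaling_curve(
            conn, 3.0 * r_e, cal_i.value, multipliers=multipliers, bg=bg,
            aux=aux, seed=seed, **curve_kw)
        row["stable"] = not (row["curve_e_only"].truncated
                             or row["curve_e_and_i"].truncated)
        out.append(row)
    return out


def combined_protocol_calibration(conn: Connectivity, *,
                                  bg: Background = Background(),
                                  seed: int = 0,
                                  spont_target: float = 5.0,
                                  response_target: float = 15.0,
                                  chr2_shift: float = 5.0,
                                  e_multiple: float = 8.0) -> dict:
    """Calibrate the paired visual+ChR2 protocol's operating point.

    Spontaneous rate is tuned to ``spont_target``; the E-only
    feedforward rate for ``response_target`` is found; the visual input
    is then the strongly feedforward-inhibited combination (E rate =
    ``e_multiple`` x the E-only rate, I rate restoring the target
    response); finally the ChR2 conductance to 33% of E cells is tuned
    to shift the mean E baseline by ``chr2_shift``.  Returns the
    calibrated quantities; raises on calibration failure.
    """
    from .calibrate import calibrate_chr2

    cal = calibrate_spontaneous(conn, spont_target, 0.5, bg=bg, seed=seed,
                                discard_s=0.5, measure_s=2.0)
    if not cal.converged:
        raise RuntimeError("spontaneous calibration failed")
    aux = (cal.extra.get("aux_pop"), cal.value)
    cal_e = find_input_for_response(conn, response_target, 1.0,
                                    ff_mode="e-only", bg=bg, aux=aux,
                                    seed=seed)
    if not cal_e.converged:
        raise RuntimeError("feedforward-E calibration failed")
    cal_i = find_input_for_response(conn, response_target, 1.0,
                                    ff_mode="i-given-e",
                                    fixed_e_rate=e_multiple * cal_e.value,
                                    bg=bg, aux=aux, seed=seed)
    if not cal_i.converged:
        raise RuntimeError("feedforward-I calibration failed")
    cal_c = calibrate_chr2(conn, "e", chr2_shift, 0.5, bg=bg, aux=aux,
                           seed=seed)
    if not cal_c.converged:
        raise RuntimeError("ChR2 calibration failed")
    return {"aux": aux, "ff_e_rate": e_multiple * cal_e.value,
            "ff_i_rate": cal_i.value, "g_chr2": cal_c.value,
            "chr2_targets": cal_c.extra["targets"],
            "spontaneous": cal.achieved, "ff_e_only_rate": cal_e.value}


def conductance_plus_visual(conn: Connectivity, *, ff_e_rate: float,
                            ff_i_rate: float, g_chr2: float,
                            chr2_targets: np.ndarray,
                            bg: Background = Background(),
                            aux: tuple = (None, 0.0),
                            target_fraction: float = 0.33,
                            n_presentations: int = 16,
                            stim_s: float = 0.5, gap_s: float = 0.5,
                            settle_s: float = 1.0,
                            seed: int = 0) -> pd.DataFrame:
    """Paired visual+ChR2 protocol; per-E-cell baselines and responses.

    Two simulations are run: one with repeated feedforward ("visual")
    input steps only, one with the same steps during a sustained ChR2
    conductance in ``chr2_targets``.  For every E cell the baseline
    rate (gaps between stimuli) and the visual response (stimulus rate
    minus preceding baseline) are measured per condition.  Returns a
    tidy frame with one row per E cell.
    """
    cycle = stim_s + gap_s
    duration = settle_s + n_presentations * cycle
    tg_e = choose_targets(conn.e_ids, target_fraction,
                          seed=conn.spec.seed + 101)
    tg_i = choose_targets(conn.i_ids, target_fraction,
                          seed=conn.spec.seed + 202)
    stim_windows = [(settle_s + k * cycle + gap_s,
                     settle_s + (k + 1) * cycle)
                    for k in range(n_presentations)]
    base_windows = [(settle_s + k * cycle, settle_s + k * cycle + gap_s)
                    for k in range(n_presentations)]
    segs_e = [(t0, t1, ff_e_rate) for t0, t1 in stim_windows]
    segs_i = [(t0, t1, ff_i_rate) for t0, t1 in stim_windows]

    def run(with_light, run_seed):
        prog = base_program(conn, bg, aux[0], aux[1])
        prog.poisson.append(PoissonDrive(tg_e, segs_e, conn.spec.w_e))
        if ff_i_rate > 0:
            prog.poisson.append(PoissonDrive(tg_i, segs_i, conn.spec.w_e))
        if with_light:
            prog.chr2.append(Chr2Drive(chr2_targets, 1e-3,
                                       duration + 1.0, g_chr2))
        rec = simulate(conn, prog, duration_s=duration, seed=run_seed)
        base = np.mean([per_neuron_rates(rec, w) for w in base_windows],
                       axis=0)[: conn.n_e]
        stim = np.mean([per_neuron_rates(rec, w) for w in stim_windows],
                       axis=0)[: conn.n_e]
        return base, stim - base

    base_off, resp_off = run(False, seed)
    base_on, resp_on = run(True, seed + 1)
    driven = np.zeros(conn.n_e, dtype=bool)
    driven[chr2_targets[chr2_targets < conn.n_e]] = True
    return pd.DataFrame({
        "unit": np.arange(conn.n_e),
        "driven": driven,
        "baseline_off": base_off, "baseline_on": base_on,
        "response_off": resp_off, "response_on": resp_on,
    })


def split_scaling_by_drive(cells: pd.DataFrame) -> dict:
    """Regression slopes of response change on baseline change.

    ``cells`` must carry baseline_off/on, response_off/on and a
    ``driven`` flag per E cell.  Returns slopes (spk/s per spk/s) for
    all E cells, the directly ChR2-driven subset and the non-driven
    subset.
    """
    dx = (cells["baseline_on"] - cells["baseline_off"]).to_numpy()
    dy = (cells["response_on"] - cells["response_off"]).to_numpy()
    driven = cells["driven"].to_numpy()

    def slope(sel):
        if sel.sum() < 2:
            raise ValueError("empty cell group in slope computation")
        x, y = dx[sel], dy[sel]
        if np.ptp(x) == 0:
            raise ValueError("degenerate baseline changes")
        return float(np.polyfit(x, y, 1)[0])

    all_sel = np.ones(len(dx), dtype=bool)
    return {"all": slope(all_sel), "driven": slope(driven),
            "non_driven": slope(~driven)}
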
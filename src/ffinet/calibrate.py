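"""Calibration of the network's operating point.

Three quantities are tuned, mirroring the experimental protocol the
model emulates:

* the spontaneous mean excitatory rate (target 5 spk/s), adjusted by an
  auxiliary Poisson input delivered to either E cells (to raise the
  rate) or I cells (to lower it), on top of a fixed unspecific
  background drive that every neuron receives;
* the feedforward input rate that evokes a given mean E response
  (target 15 spk/s);
* the ChR2 conductance amplitude that shifts the baseline rate by a
  given amount (increase for E targets, decrease for I targets).

All searches are deterministic bracketing/bisection on a scalar with
fixed simulation epochs.  Parameter points where the network is
unstable (rates saturating toward the refractory-limited maximum, or a
rate that cannot be bracketed) are flagged, not silently returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Connectivity
from .stimulus import PoissonDrive, StimulusProgram, choose_targets
from .simulate import (REFRACTORY_CEILING, mean_population_rate, simulate,
                       unstable_time)

__all__ = ["Background", "CalibrationResult", "base_program",
           "calibrate_spontaneous", "find_input_for_response",
           "calibrate_chr2", "spontaneous_rate"]


@dataclass(frozen=True)
class Background:
    """Tonic, unspecific Poisson drive delivered to every neuron.

    Each cell receives an independent Poisson train at ``rate`` (spk/s)
    with conductance increment ``weight`` (leak units).  This drive is
    part of the network's operating conditions — it stands in for the
    barrage a cortical neuron receives from sources outside the
    modelled circuit — and is held fixed while the auxiliary input is
    calibrated.
    """

    rate: float = 15.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.rate < 0 or self.weight < 0:
            raise ValueError("background rate and weight must be >= 0")


@dataclass
class CalibrationResult:
    parameter: str
    value: float
    achieved: float
    target: float
    tolerance: float
    converged: bool
    trace: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.converged and abs(self.achieved - self.target) > self.tolerance:
            raise ValueError("converged result outside tolerance")


def base_program(conn: Connectivity, bg: Background,
                 aux_pop: str | None = None, aux_rate: float = 0.0,
                 aux_weight: float | None = None) -> StimulusProgram:
    """Background drive plus the calibrated auxiliary input."""
    prog = StimulusProgram()
    if bg.rate > 0:
        prog.add_constant(np.arange(conn.n), bg.rate, bg.weight)
    if aux_pop is not None and aux_rate > 0:
        w = bg.weight if aux_weight is None else aux_weight
        prog.add_constant(conn.ids(aux_pop), aux_rate, w)
    return prog


def spontaneous_rate(conn, bg, aux_pop=None, aux_rate=0.0, *,
                     discard_s=1.0, measure_s=4.0, seed=0,
                     aux_weight=None):
    """Mean spontaneous E rate over the measurement epoch.

    Returns (rate, unstable_flag).
    """
    prog = base_program(conn, bg, aux_pop, aux_rate, aux_weight)
    rec = simulate(conn, prog, duration_s=discard_s + measure_s, seed=seed,
                   raise_on_blowup=False)
    bad = unstable_time(rec, conn.e_ids,
                        t_refrac_ms=conn.params.t_refrac_ms)
    r = mean_population_rate(rec, conn.e_ids,
                             (discard_s, discard_s + measure_s))
    return r, bad is not None


def _bisect(f, lo, hi, f_lo, f_hi, target, tol, max_iter, trace,
            increasing=True):
    """Bisection on a noisy monotone scalar map; returns (x, fx, ok)."""
    best = (lo, f_lo) if abs(f_lo - target) < abs(f_hi - target) else (hi, f_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        trace.append((mid, fm))
        if abs(fm - target) < abs(best[1] - target):
            best = (mid, fm)
        if abs(fm - target) <= tol:
            return mid, fm, True
        if (fm < target) == increasing:
            lo = mid
        else:
            hi = mid
    return best[0], best[1], abs(best[1] - target) <= tol


def calibrate_spontaneous(conn: Connectivity, target_rate: float = 5.0,
                          tolerance: float = 0.5, *,
                          bg: Background = Background(),
                          discard_s: float = 1.0, measure_s: float = 4.0,
                          seed: int = 0, max_iter: int = 12,
                          max_rate: float = 64000.0) -> CalibrationResult:
    """Tune the auxiliary Poisson rate to hit the spontaneous target.

    With no auxiliary input the network rate ``r0`` is measured; the
    auxiliary input then targets E cells if ``r0 < target`` (raising
    the rate) or I cells otherwise (lowering it), and its rate is found
    by bracketing and bisection.  Non-convergence — including saturated
    (unstable) rates and brackets that straddle a discontinuous jump,
    the signature of a bistable parameter point — is flagged in the
    result rather than raised.
    """
    trace = []
    kw = dict(discard_s=discard_s, measure_s=measure_s, seed=seed)

    def unstable_result(name, value, achieved):
        return CalibrationResult(name, value, achieved, target_rate,
                                 tolerance, False, trace,
                                 {"flag": "unstable"})

    r0, bad0 = spontaneous_rate(conn, bg, **kw)
    trace.append((0.0, r0))
    if bad0:
        return unstable_result("aux_rate", 0.0, r0)
    if abs(r0 - target_rate) <= tolerance:
        return CalibrationResult("aux_rate", 0.0, r0, target_rate,
                                 tolerance, True, trace,
                                 {"aux_pop": None, "bg": bg})
    aux_pop = "e" if r0 < target_rate else "i"
    increasing = aux_pop == "e"

    saw_unstable = False

    def f(rate):
        nonlocal saw_unstable
        r, bad = spontaneous_rate(conn, bg, aux_pop, rate, **kw)
        if bad:
            saw_unstable = True
        return r

    # bracket by doubling
    hi, f_hi = 1.0, None
    while hi <= max_rate:
        f_hi = f(hi)
        trace.append((hi, f_hi))
        if (f_hi > target_rate) == increasing:
            break
        hi *= 2.0
    else:
        return CalibrationResult("aux_rate", hi / 2.0, trace[-1][1],
                                 target_rate, tolerance, False, trace,
                                 {"flag": "target-unreachable",
                                  "aux_pop": aux_pop})
    lo, f_lo = (0.0, r0)
    value, achieved, ok = _bisect(f, lo, hi, f_lo, f_hi, target_rate,
                                  tolerance, max_iter, trace, increasing)
    if saw_unstable and not ok:
        return unstable_result("aux_rate", value, achieved)
    return CalibrationResult("aux_rate", value, achieved, target_rate,
                             tolerance, ok, trace,
                             {"aux_pop": aux_pop, "bg": bg})


def _evoked_rate(conn, bg, aux, ff_e_rate, ff_i_rate, *, fraction, seed,
                 settle_s=1.0, stim_s=1.0, measure_s=0.5, ff_weight=None):
    """Mean E rate in the tail of a single feedforward step."""
    w_ff = conn.spec.w_e if ff_weight is None else ff_weight
    prog = base_program(conn, bg, aux[0], aux[1])
    t0, t1 = settle_s, settle_s + stim_s
    if ff_e_rate > 0:
        tg = choose_targets(conn.e_ids, fraction, seed=conn.spec.seed + 101)
        prog.poisson.append(PoissonDrive(tg, [(t0, t1, ff_e_rate)], w_ff))
    if ff_i_rate > 0:
        tg = choose_targets(conn.i_ids, fraction, seed=conn.spec.seed + 202)
        prog.poisson.append(PoissonDrive(tg, [(t0, t1, ff_i_rate)], w_ff))
    rec = simulate(conn, prog, duration_s=t1, seed=seed,
                   raise_on_blowup=False)
    bad = unstable_time(rec, conn.e_ids,
                        t_refrac_ms=conn.params.t_refrac_ms)
    r = mean_population_rate(rec, conn.e_ids, (t1 - measure_s, t1))
    return r, bad is not None


def find_input_for_response(conn: Connectivity,
                            target_response: float = 15.0,
                            tolerance: float = 1.0, *,
                            ff_mode: str = "e-only",
                            fixed_e_rate: float | None = None,
                            bg: Background = Background(),
                            aux: tuple = (None, 0.0),
                            target_fraction: float = 0.33,
                            seed: int = 0, max_iter: int = 12,
                            max_rate: float = 256000.0,
                            measure_s: float = 0.5) -> CalibrationResult:
    """Find the feedforward rate evoking the target mean E response.

    ``ff_mode='e-only'`` searches the rate of Poisson input to the
    targeted E cells.  ``ff_mode='i-given-e'`` holds the E input fixed
    at ``fixed_e_rate`` and searches the rate of feedforward-inhibition
    input onto targeted I cells that brings the response down to the
    target (the recipe used to match responses with and without
    feedforward inhibition).  The response is the absolute mean E rate
    over the tail of a 1-s input step.
    """
    if ff_mode not in ("e-only", "i-given-e"):
        raise ValueError("ff_mode must be 'e-only' or 'i-given-e'")
    if ff_mode == "i-given-e" and fixed_e_rate is None:
        raise ValueError("fixed_e_rate required for ff_mode='i-given-e'")
    trace = []
    kw = dict(fraction=target_fraction, seed=seed, measure_s=measure_s)
    increasing = ff_mode == "e-only"

    def f(rate):
        if ff_mode == "e-only":
            r, _ = _evoked_rate(conn, bg, aux, rate, 0.0, **kw)
        else:
            r, _ = _evoked_rate(conn, bg, aux, fixed_e_rate, rate, **kw)
        return r

    r0 = f(0.0)
    trace.append((0.0, r0))
    if (r0 > target_response) == increasing or abs(r0 - target_response) <= tolerance:
        # already at/above target with zero input
        ok = abs(r0 - target_response) <= tolerance
        return CalibrationResult("ff_rate", 0.0, r0, target_response,
                                 tolerance, ok, trace, {"ff_mode": ff_mode})
    hi, f_hi = 250.0, None
    while hi <= max_rate:
        f_hi = f(hi)
        trace.append((hi, f_hi))
        if (f_hi > target_response) == increasing:
            break
        hi *= 2.0
    else:
        return CalibrationResult("ff_rate", hi / 2.0, trace[-1][1],
                                 target_response, tolerance, False, trace,
                                 {"flag": "target-unreachable",
                                  "ff_mode": ff_mode})
    value, achieved, ok = _bisect(f, 0.0, hi, r0, f_hi, target_response,
                                  tolerance, max_iter, trace, increasing)
    return CalibrationResult("ff_rate", value, achieved, target_response,
                             tolerance, ok, trace, {"ff_mode": ff_mode})


def calibrate_chr2(conn: Connectivity, target_population: str = "e",
                   target_shift: float = 5.0, tolerance: float = 0.5, *,
                   fold_decrease: float | None = None,
                   bg: Background = Background(),
                   aux: tuple = (None, 0.0),
                   target_fraction: float = 0.33,
                   seed: int = 0, max_iter: int = 12,
                   discard_s: float = 1.0, measure_s: float = 2.0,
                   max_amp: float = 64.0) -> CalibrationResult:
    """Find the ChR2 conductance amplitude for a target baseline change.

    For E targets the target is an additive increase of the mean E
    spontaneous rate by ``target_shift`` spk/s.  For I targets pass
    ``fold_decrease`` (e.g. 2.0 to halve the baseline); the amplitude
    is tuned so that baseline/achieved equals that factor, emulating
    optogenetic activation of PV cells.
    """
    from .stimulus import Chr2Drive

    if target_population not in ("e", "i"):
        raise ValueError("target_population must be 'e' or 'i'")
    r_base, bad = spontaneous_rate(conn, bg, aux[0], aux[1],
                                   discard_s=discard_s,
                                   measure_s=measure_s, seed=seed)
    if bad:
        return CalibrationResult("g_chr2", 0.0, r_base, target_shift,
                                 tolerance, False, [],
                                 {"flag": "unstable"})
    if target_population == "e":
        goal = r_base + target_shift
        increasing = True
    else:
        if fold_decrease is None or fold_decrease <= 1.0:
            raise ValueError("fold_decrease > 1 required for I targets")
        goal = r_base / fold_decrease
        increasing = False
    tg = choose_targets(conn.ids(target_population), target_fraction,
                        seed=conn.spec.seed + 303)
    trace = []

    def f(amp):
        prog = base_program(conn, bg, aux[0], aux[1])
        dur = discard_s + measure_s
        prog.chr2.append(Chr2Drive(tg, 1e-3, dur + 1.0, amp))
        rec = simulate(conn, prog, duration_s=dur, seed=seed,
                       raise_on_blowup=False)
        return mean_population_rate(rec, conn.e_ids,
                                    (discard_s, discard_s + measure_s))

    hi, f_hi = 0.125, None
    while hi <= max_amp:
        f_hi = f(hi)
        trace.append((hi, f_hi))
        if (f_hi > goal) == increasing:
            break
        hi *= 2.0
    else:
        return CalibrationResult("g_chr2", hi / 2.0, trace[-1][1], goal,
                                 tolerance, False, trace,
                                 {"flag": "target-unreachable"})
    value, achieved, ok = _bisect(f, 0.0, hi, r_base, f_hi, goal,
                                  tolerance, max_iter, trace, increasing)
    return CalibrationResult("g_chr2", value, achieved, goal, tolerance,
                             ok, trace,
                             {"baseline": r_base, "targets": tg,
                              "target_population": target_population})
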
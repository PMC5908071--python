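"""Input programs: Poisson feedforward drives and conductance (ChR2) steps.

A :class:`StimulusProgram` is a list of Poisson drive channels plus a
list of conductance channels.  Each Poisson channel delivers independent
Poisson spike trains to its target cells (one process per cell at the
channel's aggregate per-cell rate), incrementing the excitatory or
inhibitory conductance by the channel weight per arrival.  Conductance
channels model ChR2-like photocurrents: the target cells' g_ChR2 ramps
linearly to the programmed amplitude over ``ramp_ms`` (default 2 ms) at
onset and back to zero at offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PoissonDrive", "Chr2Drive", "StimulusProgram",
           "choose_targets", "staircase_segments"]


@dataclass
class PoissonDrive:
    """Piecewise-constant-rate Poisson input onto a set of cells.

    ``segments`` is a list of ``(t_start_s, t_end_s, rate_spk_s)``; the
    rate is the aggregate arrival rate per targeted cell.  Outside all
    segments the rate is zero.
    """

    targets: np.ndarray
    segments: list
    weight: float
    conductance: str = "e"  # which conductance the arrivals increment

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.int64)
        if self.conductance not in ("e", "i"):
            raise ValueError("conductance must be 'e' or 'i'")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        for t0, t1, r in self.segments:
            if r < 0:
                raise ValueError("rates must be >= 0")
            if not t0 < t1:
                raise ValueError("segment onset must precede offset")

    def rate_per_step(self, n_steps: int, dt_s: float) -> np.ndarray:
        out = np.zeros(n_steps, dtype=np.float64)
        for t0, t1, r in self.segments:
            i0 = int(round(t0 / dt_s))
            i1 = n_steps if np.isinf(t1) else min(int(round(t1 / dt_s)), n_steps)
            out[i0:i1] = r
        return out


@dataclass
class Chr2Drive:
    """Conductance step (leak units) with linear 2-ms on/off ramps."""

    targets: np.ndarray
    onset_s: float
    offset_s: float
    amplitude: float
    ramp_ms: float = 2.0

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.int64)
        if not self.onset_s < self.offset_s:
            raise ValueError("onset must precede offset")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def amp_per_step(self, n_steps: int, dt_s: float) -> np.ndarray:
        t = np.arange(n_steps) * dt_s
        ramp = max(self.ramp_ms * 1e-3, dt_s)
        up = np.clip((t - self.onset_s) / ramp, 0.0, 1.0)
        down = np.clip((t - self.offset_s) / ramp, 0.0, 1.0)
        return self.amplitude * (up - down)


@dataclass
class StimulusProgram:
    """All external inputs for one simulation run."""

    poisson: list = field(default_factory=list)
    chr2: list = field(default_factory=list)
    target_fraction: float = 0.33

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in (0, 1]")

    def add_constant(self, targets, rate, weight, conductance="e",
                     t0=0.0, t1=np.inf) -> "StimulusProgram":
        """Append a constant-rate Poisson drive (e.g. calibration input)."""
        if rate > 0:
            self.poisson.append(
                PoissonDrive(targets, [(t0, t1, rate)], weight, conductance)
            )
        return self


def choose_targets(ids: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Random subset of ``ids`` of size fraction*len(ids) (>=1)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    k = max(1, int(round(fraction * len(ids))))
    return np.sort(rng.choice(ids, size=k, replace=False))


def staircase_segments(t0: float, step_dur: float, base_rate: float,
                       multipliers) -> list:
    """Contiguous rate steps base_rate*m for m in multipliers."""
    segs = []
    t = t0
    for m in multipliers:
        segs.append((t, t + step_dur, base_rate * m))
        t += step_dur
    return segs
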
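"""Time-stepped simulation of the conductance-based LIF network.

The integration scheme is forward Euler for the membrane potential at a
fixed step (50 us by default) with exact exponential decay of the
synaptic conductances between events.  On a threshold crossing the
membrane potential is clamped to the reset potential for the absolute
refractory period while conductances keep evolving.  Poisson channel
arrivals are drawn by aggregating each channel's per-cell processes
into one population process and assigning arrivals uniformly over the
channel's targets, which is distributionally identical to independent
per-cell processes.

The inner loop is compiled with numba; all randomness inside the kernel
comes from one seeded stream, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import Connectivity
from .stimulus import StimulusProgram

__all__ = ["SpikeRecord", "simulate", "mean_population_rate",
           "per_neuron_rates", "per_neuron_counts", "isi_cv",
           "unstable_time", "InstabilityError", "REFRACTORY_CEILING"]


class InstabilityError(RuntimeError):
    """Numerical blow-up during integration."""

    def __init__(self, time_s: float):
        self.time_s = time_s
        super().__init__(f"non-finite state at t={time_s:.4f} s")


def REFRACTORY_CEILING(t_refrac_ms: float = 3.0) -> float:
    """Hard upper bound on sustainable firing rate (spk/s)."""
    return 1000.0 / t_refrac_ms


@njit(cache=True)
def _run_kernel(n_steps, n, n_e, dt_s,
                v, ge, gi, gchr2, refrac,
                de, di, dt_over_tau, g_leak, e_rest, v_th, e_e, e_i,
                ref_steps,
                indptr, indices, weights,
                pch_indptr, pch_targets, pch_weight, pch_isgi, pch_rate,
                cch_indptr, cch_targets, cch_amp,
                seed, rec_ids, vm_out):
    np.random.seed(seed)
    n_pch = pch_indptr.shape[0] - 1
    n_cch = cch_indptr.shape[0] - 1
    n_rec = rec_ids.shape[0]
    cap = 1 << 16
    sp_step = np.empty(cap, dtype=np.int64)
    sp_id = np.empty(cap, dtype=np.int64)
    n_sp = 0
    spiked = np.empty(n, dtype=np.int64)
    for t in range(n_steps):
        # ChR2 conductance updates (only when the programmed amp changes)
        for c in range(n_cch):
            prev = cch_amp[c, t - 1] if t > 0 else 0.0
            delta = cch_amp[c, t] - prev
            if delta != 0.0:
                for k in range(cch_indptr[c], cch_indptr[c + 1]):
                    gchr2[cch_targets[k]] += delta
        # Poisson channel arrivals (aggregated population process)
        for c in range(n_pch):
            r = pch_rate[c, t]
            if r > 0.0:
                lo = pch_indptr[c]
                ntg = pch_indptr[c + 1] - lo
                k_ev = np.random.poisson(r * dt_s * ntg)
                w = pch_weight[c]
                if pch_isgi[c]:
                    for _ in range(k_ev):
                        gi[pch_targets[lo + np.random.randint(ntg)]] += w
                else:
                    for _ in range(k_ev):
                        ge[pch_targets[lo + np.random.randint(ntg)]] += w
        # membrane update + threshold
        n_spiked = 0
        for i in range(n):
            ge[i] *= de
            gi[i] *= di
            if refrac[i] > 0:
                refrac[i] -= 1
                v[i] = e_rest
                continue
            vi = v[i]
            vi += -dt_over_tau * (
                g_leak * (vi - e_rest)
                + (gchr2[i] + ge[i]) * (vi - e_e)
                + gi[i] * (vi - e_i)
            )
            if vi >= v_th:
                v[i] = e_rest
                refrac[i] = ref_steps
                spiked[n_spiked] = i
                n_spiked += 1
            else:
                v[i] = vi
        if n_spiked > 0:
            if not np.isfinite(v[spiked[0]]):
                return sp_step[:n_sp], sp_id[:n_sp], t
            if n_sp + n_spiked > cap:
                while n_sp + n_spiked > cap:
                    cap *= 2
                new_step = np.empty(cap, dtype=np.int64)
                new_id = np.empty(cap, dtype=np.int64)
                new_step[:n_sp] = sp_step[:n_sp]
                new_id[:n_sp] = sp_id[:n_sp]
                sp_step = new_step
                sp_id = new_id
            for s in range(n_spiked):
                i = spiked[s]
                sp_step[n_sp] = t
                sp_id[n_sp] = i
                n_sp += 1
                if i < n_e:
                    for k in range(indptr[i], indptr[i + 1]):
                        ge[indices[k]] += weights[k]
                else:
                    for k in range(indptr[i], indptr[i + 1]):
                        gi[indices[k]] += weights[k]
        for r_i in range(n_rec):
            vm_out[r_i, t] = v[rec_ids[r_i]]
        if t % 20000 == 0 and not np.isfinite(v).all():
            return sp_step[:n_sp], sp_id[:n_sp], t
    return sp_step[:n_sp], sp_id[:n_sp], -1


@dataclass
class SpikeRecord:
    """Spike output of one simulation run.

    ``ids``/``times`` are parallel arrays sorted by time.  ``vm`` maps a
    sampled neuron id to its membrane-potential trace (one sample per
    integration step).
    """

    ids: np.ndarray
    times: np.ndarray
    duration_s: float
    dt_us: float
    n_neurons: int
    n_e: int
    vm: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.ids == neuron]

    def counts_per_neuron(self, window=None) -> np.ndarray:
        t0, t1 = window or (0.0, self.duration_s)
        sel = (self.times >= t0) & (self.times < t1)
        return np.bincount(self.ids[sel], minlength=self.n_neurons)


def simulate(conn: Connectivity, program: StimulusProgram,
             duration_s: float, dt_us: float = 50.0, seed: int = 0,
             record_vm: np.ndarray | None = None,
             raise_on_blowup: bool = True) -> SpikeRecord:
    """Run the network under ``program`` for ``duration_s`` seconds.

    ``record_vm`` optionally lists neuron ids whose membrane potential
    is sampled every step.  Raises :class:`InstabilityError` if the
    state becomes non-finite (unless ``raise_on_blowup`` is False, in
    which case the truncated record is returned with
    ``meta['blowup_time_s']`` set).
    """
    p = conn.params
    n = conn.n
    dt_s = dt_us * 1e-6
    dt_ms = dt_us * 1e-3
    n_steps = int(round(duration_s / dt_s))
    indptr, indices, weights = conn.merged_csr()

    ss = np.random.SeedSequence(seed)
    init_seed, kern_seed = [int(s) for s in ss.generate_state(2)]
    rng = np.random.default_rng(init_seed)
    v = rng.uniform(p.e_rest, p.v_thresh, size=n)
    ge = np.zeros(n)
    gi = np.zeros(n)
    gchr2 = np.zeros(n)
    refrac = np.zeros(n, dtype=np.int64)

    # compile Poisson channels
    pch = list(program.poisson)
    if pch:
        pch_indptr = np.cumsum([0] + [len(c.targets) for c in pch]).astype(np.int64)
        pch_targets = np.concatenate([c.targets for c in pch]).astype(np.int64)
        pch_weight = np.array([c.weight for c in pch])
        pch_isgi = np.array([c.conductance == "i" for c in pch], dtype=np.bool_)
        pch_rate = np.stack([c.rate_per_step(n_steps, dt_s) for c in pch])
    else:
        pch_indptr = np.zeros(1, dtype=np.int64)
        pch_targets = np.zeros(0, dtype=np.int64)
        pch_weight = np.zeros(0)
        pch_isgi = np.zeros(0, dtype=np.bool_)
        pch_rate = np.zeros((0, n_steps))
    cch = list(program.chr2)
    if cch:
        cch_indptr = np.cumsum([0] + [len(c.targets) for c in cch]).astype(np.int64)
        cch_targets = np.concatenate([c.targets for c in cch]).astype(np.int64)
        cch_amp = np.stack([c.amp_per_step(n_steps, dt_s) for c in cch])
    else:
        cch_indptr = np.zeros(1, dtype=np.int64)
        cch_targets = np.zeros(0, dtype=np.int64)
        cch_amp = np.zeros((0, n_steps))

    rec_ids = (np.asarray(record_vm, dtype=np.int64)
               if record_vm is not None else np.zeros(0, dtype=np.int64))
    vm_out = np.empty((len(rec_ids), n_steps))

    sp_step, sp_id, blow_t = _run_kernel(
        n_steps, n, conn.n_e, dt_s,
        v, ge, gi, gchr2, refrac,
        np.exp(-dt_ms / p.tau_ge_ms), np.exp(-dt_ms / p.tau_gi_ms),
        dt_ms / p.tau_m_ms, p.g_leak, p.e_rest, p.v_thresh, p.e_e, p.e_i,
        int(round(p.t_refrac_ms / dt_ms)),
        indptr, indices, weights,
        pch_indptr, pch_targets, pch_weight, pch_isgi, pch_rate,
        cch_indptr, cch_targets, cch_amp,
        kern_seed % (2**31), rec_ids, vm_out)

    if blow_t >= 0 and raise_on_blowup:
        raise InstabilityError(blow_t * dt_s)
    rec = SpikeRecord(
        ids=np.asarray(sp_id), times=np.asarray(sp_step) * dt_s,
        duration_s=duration_s, dt_us=dt_us, n_neurons=n, n_e=conn.n_e,
        vm={int(i): vm_out[k] for k, i in enumerate(rec_ids)},
        meta={"seed": seed, "init_seed": init_seed,
              "kernel_seed": kern_seed % (2**31),
              "connectivity_seed": conn.spec.seed},
    )
    if blow_t >= 0:
        rec.meta["blowup_time_s"] = blow_t * dt_s
    return rec


def mean_population_rate(rec: SpikeRecord, population: np.ndarray,
                         window: tuple[float, float]) -> float:
    """Mean firing rate (spk/s) of ``population`` within ``window``.

    Total spike count of the population in [t0, t1) divided by
    population size and window length.
    """
    t0, t1 = window
    if not (t1 > t0):
        raise ValueError("window must have positive length")
    if t0 < 0 or t1 > rec.duration_s + 1e-12:
        raise ValueError("window outside simulation duration")
    population = np.asarray(population)
    mask = np.zeros(rec.n_neurons, dtype=bool)
    mask[population] = True
    sel = (rec.times >= t0) & (rec.times < t1)
    count = int(mask[rec.ids[sel]].sum())
    return count / (len(population) * (t1 - t0))


def per_neuron_counts(rec: SpikeRecord, window: tuple[float, float]) -> np.ndarray:
    return rec.counts_per_neuron(window)


def per_neuron_rates(rec: SpikeRecord, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    return rec.counts_per_neuron(window) / (t1 - t0)


def isi_cv(rec: SpikeRecord, ids: np.ndarray, min_spikes: int = 5) -> float:
    """Median ISI coefficient of variation over ``ids``.

    Neurons with fewer than ``min_spikes`` spikes are skipped; NaN if
    no neuron qualifies.
    """
    order = np.argsort(rec.ids, kind="stable")
    sids = rec.ids[order]
    stimes = rec.times[order]
    bounds = np.searchsorted(sids, [np.asarray(ids), np.asarray(ids) + 1])
    cvs = []
    for lo, hi in zip(bounds[0], bounds[1]):
        if hi - lo >= min_spikes:
            isi = np.diff(np.sort(stimes[lo:hi]))
            if isi.mean() > 0:
                cvs.append(isi.std() / isi.mean())
    return float(np.median(cvs)) if cvs else float("nan")


def unstable_time(rec: SpikeRecord, population: np.ndarray,
                  frac_of_max: float = 0.8, window_s: float = 0.2,
                  t_refrac_ms: float = 3.0) -> float | None:
    """First time the population rate exceeds frac_of_max of the
    refractory-limited maximum for a sustained ``window_s``, or None.
    """
    if "blowup_time_s" in rec.meta:
        return float(rec.meta["blowup_time_s"])
    bin_s = 0.01
    edges = np.arange(0.0, rec.duration_s + bin_s, bin_s)
    population = np.asarray(population)
    mask = np.zeros(rec.n_neurons, dtype=bool)
    mask[population] = True
    t = rec.times[mask[rec.ids]]
    counts, _ = np.histogram(t, bins=edges)
    rate = counts / (len(population) * bin_s)
    k = max(1, int(round(window_s / bin_s)))
    thresh = frac_of_max * REFRACTORY_CEILING(t_refrac_ms)
    run = 0
    for j, r in enumerate(rate):
        run = run + 1 if r > thresh else 0
        if run >= k:
            return float(edges[j + 1] - window_s)
    return None
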
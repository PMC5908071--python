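"""Construction of sparse recurrent conductance-based E/I networks.

A network has ``n_e`` excitatory and ``n_i`` inhibitory leaky
integrate-and-fire neurons.  Every ordered pair of distinct neurons is
connected independently with probability ``sparsity`` ("balancing"
connections); optional *extra* connection sets add further random
connections between chosen populations, drawn independently of the
balancing set.  Neuron ids are global: excitatory cells occupy
``0 .. n_e-1`` and inhibitory cells ``n_e .. n_e+n_i-1``.

Synaptic weights are dimensionless conductances in units of the leak
conductance; a presynaptic spike increments the target's excitatory or
inhibitory conductance (by source population) instantaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "NeuronParams",
    "ExtraSet",
    "NetworkSpec",
    "Connectivity",
    "build_connectivity",
]

_POPS = ("e", "i")


@dataclass(frozen=True)
class NeuronParams:
    """Single-neuron parameters of the conductance-based LIF model.

    Membrane potentials are in mV, time constants in ms, conductances in
    units of the leak conductance.  The membrane potential obeys

        dVm/dt = -(1/tau_m) [ g_leak (Vm - E_rest) + g_ChR2 (Vm - E_e)
                              + g_e (Vm - E_e) + g_i (Vm - E_i) ]

    and is reset to ``e_rest`` for ``t_refrac_ms`` after a threshold
    crossing.  Synaptic conductances decay exponentially with
    ``tau_ge_ms`` / ``tau_gi_ms``.
    """

    e_rest: float = -60.0
    v_thresh: float = -50.0
    t_refrac_ms: float = 3.0
    tau_m_ms: float = 20.0
    e_e: float = 0.0
    e_i: float = -80.0
    tau_ge_ms: float = 5.0
    tau_gi_ms: float = 10.0
    g_leak: float = 1.0

    def __post_init__(self) -> None:
        if not (self.e_i < self.e_rest < self.v_thresh < self.e_e):
            raise ValueError(
                "reversal/threshold ordering must satisfy "
                "E_i < E_rest < V_thresh < E_e"
            )
        for name in ("tau_m_ms", "tau_ge_ms", "tau_gi_ms", "t_refrac_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.g_leak <= 0:
            raise ValueError("g_leak must be > 0")


@dataclass(frozen=True)
class ExtraSet:
    """An added random connection set between two populations.

    ``weight`` is an absolute conductance increment (leak units), *not*
    a fraction of the balancing weight.
    """

    source: str  # 'e' or 'i'
    target: str  # 'e' or 'i'
    sparsity: float
    weight: float

    def __post_init__(self) -> None:
        if self.source not in _POPS or self.target not in _POPS:
            raise ValueError("populations must be 'e' or 'i'")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in [0, 1]")
        if self.weight < 0:
            raise ValueError("extra-set weight must be >= 0")


@dataclass(frozen=True)
class NetworkSpec:
    """Population sizes, sparsity and synaptic weights of a network.

    Default weights give a single EPSP of ~1 mV at Vm = -65 mV with the
    default neuron parameters, with inhibitory synapses four times
    stronger than excitatory ones.
    """

    n_e: int = 8000
    n_i: int = 2000
    sparsity: float = 0.02
    w_e: float = 0.1
    w_i: float = 0.8
    extra_sets: tuple[ExtraSet, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_e <= 0 or self.n_i <= 0:
            raise ValueError("population sizes must be positive")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in [0, 1]")
        if self.w_e < 0 or self.w_i < 0:
            raise ValueError("synaptic weights must be >= 0")
        object.__setattr__(self, "extra_sets", tuple(self.extra_sets))

    @property
    def n(self) -> int:
        return self.n_e + self.n_i

    def with_extra(self, *extra: ExtraSet) -> "NetworkSpec":
        """Return a copy with additional connection sets appended."""
        return replace(self, extra_sets=self.extra_sets + tuple(extra))


def _random_block(
    rng: np.random.Generator,
    n_src: int,
    n_tgt: int,
    p: float,
    same_pop: bool,
) -> sp.csr_matrix:
    """Bernoulli(p) adjacency block, excluding self-pairs when same_pop."""
    if p == 0.0:
        return sp.csr_matrix((n_src, n_tgt), dtype=np.float64)
    n_choices = n_tgt - 1 if same_pop else n_tgt
    counts = rng.binomial(n_choices, p, size=n_src)
    indptr = np.zeros(n_src + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    for row in range(n_src):
        k = counts[row]
        if k == 0:
            continue
        tgt = rng.choice(n_choices, size=k, replace=False)
        if same_pop:
            tgt = np.where(tgt >= row, tgt + 1, tgt)
        indices[indptr[row] : indptr[row + 1]] = np.sort(tgt)
    data = np.ones(indptr[-1], dtype=np.float64)
    return sp.csr_matrix((data, indices, indptr), shape=(n_src, n_tgt))


@dataclass
class Connectivity:
    """Realized random connectivity of a network.

    ``blocks`` maps (source_pop, target_pop) to the 0/1 balancing
    adjacency; ``extra_blocks`` holds one adjacency per extra set.  The
    merged weighted graph used by the simulator is exposed through
    :meth:`merged_csr` (rows = global source id; weights already include
    the per-set synaptic weight, with coincident edges summed).
    """

    spec: NetworkSpec
    params: NeuronParams
    blocks: dict
    extra_blocks: list

    @property
    def n_e(self) -> int:
        return self.spec.n_e

    @property
    def n_i(self) -> int:
        return self.spec.n_i

    @property
    def n(self) -> int:
        return self.spec.n

    @property
    def e_ids(self) -> np.ndarray:
        return np.arange(self.n_e)

    @property
    def i_ids(self) -> np.ndarray:
        return np.arange(self.n_e, self.n)

    def ids(self, pop: str) -> np.ndarray:
        return self.e_ids if pop == "e" else self.i_ids

    def mean_in_degree(self, src: str, tgt: str) -> float:
        """Mean realized balancing in-degree of tgt cells from src."""
        block = self.blocks[(src, tgt)]
        return float(block.sum(axis=0).mean())

    def mean_extra_in_degree(self, index: int) -> float:
        return float(self.extra_blocks[index].sum(axis=0).mean())

    def extra_input_fraction(self, index: int) -> float:
        """Extra-set input as a fraction of balancing input to one cell.

        Ratio of expected (in-degree x weight) of the extra set to that
        of the balancing connections from the same source population —
        the axis normalization used in local-connectivity sweeps.
        """
        ex = self.spec.extra_sets[index]
        n_src = self.spec.n_e if ex.source == "e" else self.spec.n_i
        base_w = self.spec.w_e if ex.source == "e" else self.spec.w_i
        denom = self.spec.sparsity * n_src * base_w
        if denom == 0:
            raise ValueError("balancing input is zero; fraction undefined")
        return ex.sparsity * n_src * ex.weight / denom

    def merged_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(indptr, indices, weights) of the merged weighted graph."""
        if getattr(self, "_merged", None) is None:
            n = self.n
            mats = []
            offset = {"e": 0, "i": self.n_e}
            size = {"e": self.n_e, "i": self.n_i}

            def expand(block, src, tgt, weight):
                coo = block.tocoo()
                rows = coo.row + offset[src]
                cols = coo.col + offset[tgt]
                data = np.full(coo.nnz, weight, dtype=np.float64)
                return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

            for (src, tgt), block in self.blocks.items():
                w = self.spec.w_e if src == "e" else self.spec.w_i
                mats.append(expand(block, src, tgt, w))
            for ex, block in zip(self.spec.extra_sets, self.extra_blocks):
                if ex.weight > 0:
                    mats.append(expand(block, ex.source, ex.target, ex.weight))
            merged = sum(mats[1:], start=mats[0]).tocsr() if mats else sp.csr_matrix((n, n))
            merged.sum_duplicates()
            self._merged = (
                merged.indptr.astype(np.int64),
                merged.indices.astype(np.int64),
                merged.data.astype(np.float64),
            )
        return self._merged


def build_connectivity(
    spec: NetworkSpec, params: NeuronParams | None = None
) -> Connectivity:
    """Draw the random connectivity for ``spec``.

    Each ordered pair (excluding self-pairs) is an independent
    Bernoulli(sparsity) draw; each extra set is drawn independently with
    its own sparsity.  Deterministic given ``spec.seed``.
    """
    params = params or NeuronParams()
    ss = np.random.SeedSequence(spec.seed)
    streams = ss.spawn(4 + len(spec.extra_sets))
    sizes = {"e": spec.n_e, "i": spec.n_i}
    blocks = {}
    for k, (src, tgt) in enumerate(
        [("e", "e"), ("e", "i"), ("i", "e"), ("i", "i")]
    ):
        rng = np.random.default_rng(streams[k])
        blocks[(src, tgt)] = _random_block(
            rng, sizes[src], sizes[tgt], spec.sparsity, src == tgt
        )
    extra_blocks = []
    for j, ex in enumerate(spec.extra_sets):
        rng = np.random.default_rng(streams[4 + j])
        extra_blocks.append(
            _random_block(
                rng, sizes[ex.source], sizes[ex.target], ex.sparsity,
                ex.source == ex.target,
            )
        )
    return Connectivity(spec=spec, params=params, blocks=blocks,
                        extra_blocks=extra_blocks)
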
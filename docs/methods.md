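# Methods

## Model

Neurons are conductance-based leaky integrate-and-fire units. The
membrane equation divides every conductance term by the membrane time
constant with the leak inside the bracket, so conductances are
dimensionless multiples of the leak (`g_leak = 1`). Constants:
`E_rest = −60 mV`, `V_thresh = −50 mV`, `E_e = 0 mV`, `E_i = −80 mV`,
`τ_m = 20 ms`, `τ_ge = 5 ms`, `τ_gi = 10 ms`, absolute refractory
period 3 ms. During refractoriness the membrane is clamped to
`E_rest`; synaptic conductances keep decaying and accumulating, the
simplest contract consistent with a reset-and-hold refractory.

Connectivity is an independent Bernoulli(p) draw per ordered pair of
distinct neurons ("balancing" connections), with optional extra
connection sets drawn independently at their own sparsity and weight.
Coincident edges from different sets act as separate synapses (their
conductance increments add). Self-connections are excluded.

### Integration

Forward Euler for the membrane at dt = 50 µs; exact exponential decay
for the synaptic conductances between events (this removes the only
stiff terms, so Euler at the stated step is accurate — the
single-neuron f–I curve matches the analytic conductance-LIF solution
to well under 1%). Poisson channels are realized by drawing the
aggregate event count of each channel per step and assigning events
uniformly over the channel's targets; by the thinning property this is
distributionally identical to independent per-cell processes and is
what makes the compiled kernel fast. All randomness in a run derives
from one seed (separate streams for connectivity, initial membrane
potentials — uniform between rest and threshold — and the kernel);
identical seeds give bit-identical spike records.

### Synaptic weights

The printed equation fixes the units but not the weights. Defaults are
`w_e = 0.1` (a single EPSP of ~1 mV at Vm = −65 mV, so tens of EPSPs
are needed to reach threshold) and `w_i = 0.8`. The inhibitory weight
is deliberately 8× the excitatory one: at ratios around 4 the
excitatory feedback dominates and the network has no stable low-rate
state (the spontaneous rate jumps discontinuously from silence to
>20 spk/s as drive increases), while at ratio 8 the rate varies
smoothly through 5 spk/s. Both weights are config-exposed; the scaling
conclusions were checked at 1× and 2× overall strength and 5–20%
sparsity (`sweep_sparsity_strength`).

### Background drive and spontaneous-state calibration

Every neuron receives an independent background Poisson train
(default 15 spk/s, unitary weight 1.0 — large, infrequent kicks).
This drive stands in for the barrage cortical neurons receive from
sources outside the modelled circuit, and it is what keeps the
spontaneous state asynchronous and irregular at 5 spk/s: purely
recurrently sustained activity in this architecture extinguishes below
~7 spk/s, and weakly-driven homogeneous networks instead fall into
synchronized population bursts. With the background in place the
calibrated state has a median ISI CV near 1 and population-rate
fluctuations (10-ms bins) smaller than the mean rate.

On top of the fixed background, the spontaneous calibration tunes one
auxiliary Poisson input targeting either E cells (to raise the rate)
or I cells (to lower it) by deterministic bracketing and bisection,
with 4-s measurement epochs after a 1-s discard at full scale
(shorter, config-exposed epochs for reduced networks) and a 0.5 spk/s
tolerance. Saturated rates (above 80% of the refractory-limited
333 spk/s maximum for 200 ms) and unbracketable targets — the
signature of unstable or bistable parameter points — are flagged, and
flagged points are masked in sweeps rather than reported.

## Response-scaling measurements

A staircase stimulus steps the feedforward rate through multiples
{1, 2, 3, 4} of a base rate, 1 s per step, with the mean E rate over
the final 500 ms of each step as the step response (the first 500 ms
absorbs the transient). Linearity is judged on increments: the delta
of step k is its rate minus the previous step's rate, and the percent
change colour value is the second delta relative to the first
(0% = linear, negative = sublinear). First responses outside 5–20
spk/s are masked, as are unstable cells; prior rates above 50 spk/s
are flagged as refractory-confounded.

Matched operating points follow the experimental recipe: the E-only
rate `R_E` giving a 15 spk/s response is found first; the
feedforward-inhibition configuration fixes the E rate at `3 R_E` and
finds the I-target rate restoring a 15 spk/s response, so both
staircases start from the same response and spontaneous rate.

Local-connectivity sweeps hold the auxiliary input (calibrated once on
the balanced network) and the feedforward rates fixed across the grid;
axis values are expressed as the fractional change in total synaptic
input a cell receives from one population (extra in-degree × weight
over balancing in-degree × weight). In this model the sign pattern —
strengthened I→I makes scaling strongly sublinear only when
feedforward input also reaches I cells — is expressed at +10% extra
I→I input; at +20% the spontaneous state leaves the 5–20 spk/s
analysis band under the fixed operating point (and is bistable under
per-cell recalibration), so those cells are masked. Per-cell
recalibration is available via `recalibrate=True`.

The combined conductance-plus-spiking protocol pairs repeated
feedforward steps ("visual") with a sustained ChR2 conductance in 33%
of E cells, calibrated to a +5 spk/s mean baseline shift. The visual
input uses a strongly feedforward-inhibited composition (E rate = 8×
the E-only 15 spk/s rate, I rate restoring 15 spk/s); the paper-scale
composition of this input is not printed and was fitted to data there,
and this choice places the model in the reported moderately-sublinear
regime. Per-cell regression of visual-response change on baseline
change then yields slopes near −0.6 to −0.8 spk/s per spk/s, with
cells receiving no direct ChR2 input showing more negative slopes than
directly driven ones — recurrent inhibition, not direct drive, carries
the sublinearity.

## Spike-train analysis

Responses are spike counts in [onset+25 ms, onset+200 ms) with a
matched 175-ms baseline ending at onset; rates are counts/0.175 s and
SEMs are across presentations. A unit is significantly nonlinear when
a two-sample two-tailed KS test on its per-presentation
baseline-subtracted response counts, with versus without light, gives
p < 0.01; the exact null distribution is used below 30 presentations
per condition. The sign of the mean difference assigns supra- vs
sublinear. Filters: shanks whose mean visual response is ≤0.2 spk/s
are dropped first, then units individually below 0.2 spk/s. Shanks
are ranked by mean ChR2-induced baseline shift and split into three
contiguous groups (ties broken by shank id; group sizes can differ
slightly because the split is by shank). LOWESS summaries use span
0.6 with a 1000-resample bootstrap over units for 95% CIs; PSTHs are
10-ms histograms smoothed by LOWESS without robustness iterations
(robust reweighting would flatten genuine sharp transients).

## Synthetic recordings

The generator reproduces the protocol timing exactly: stimuli every
1 s in sets of 10, light on alternating sets from 500 ms before the
first stimulus, total pulse 0.5 + 9×1 + 0.2 + 0.5 = 10.2 s, 1-s delay
between sets. Each unit is an inhomogeneous Poisson process: baseline
+ ChR2 shift while the light is on + a raised-cosine evoked transient
(115 ms FWHM) scaled by a saturating (Naka–Rushton, c50 = 20%)
contrast function and by the unit's additivity coefficient c under
light. Rates are clipped at zero with a recorded flag. Expected
window counts per presentation are stored as ground truth, so
analysis estimates can be checked for bias, and a perfectly additive
population (c = 1) calibrates the classifier's false-positive rate.
What the generator does not emulate: spike-sorting artifacts,
refractory structure within units, correlated noise across units, and
slow nonstationarities — passing tests therefore validate the
analysis logic, not robustness to those features of real recordings.

Down-scaled fixture networks shrink both populations by a scale
factor while raising sparsity by its inverse, preserving each cell's
expected in-degree × weight (weights take over if sparsity would
exceed 0.5). The standard fixture (scale 0.2: 1 600 E / 400 I, 10%
sparsity) calibrates to the same 5 spk/s spontaneous state and shows
the same scaling phenomenology as the full network.

## Problem sizes used in tests

The test suite and the acceptance script run the full 10 000-neuron
network only for the spontaneous calibration; scaling rows, the
local-connectivity comparison and the combined protocol run at the
1 600/400 fixture scale with 2–3 seeds per comparison, chosen as the
smallest sizes at which the orderings under test are stable across
seeds.

## Known limitations

No synaptic delays, short-term plasticity or dendritic nonlinearity
(deliberately: summation effects here are purely network-level). The
spontaneous state requires the background drive; a purely
self-sustained 5 spk/s asynchronous state does not exist in this
integrator's parameter space. The strongly disinhibited corner of the
local-connectivity plane (extra I→I ≳ 15–20%) is bistable rather than
gradually sublinear, so the published pattern there is expressed at
somewhat smaller I→I increments. Heat maps are reproduced as sign
patterns and masks, not value-for-value.
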
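# Methods

`mauthnet` is a conductance-based model of the bilateral Mauthner (M-cell)
escape circuit of larval zebrafish, together with the calibration,
perturbation and statistical analyses that surround it. This note records
the model equations, the parameter choices and their rationale, the
numerical methods, and what the synthetic-data stage does and does not
emulate.

## The circuit model

Each brain side contains one M-cell and a pool of 30 feedforward (FF)
glycinergic interneurons, both modeled as conductance-based leaky
integrate-and-fire (LIF) neurons, and 30 VIIIth-ganglion auditory afferents
modeled with Hodgkin–Huxley (HH) dynamics. The LIF membrane follows

C dV/dt = (E_rest − V)/R_m + Σ g_syn(t)·(E_rev − V) + Σ g_gap·(V_pre − V) + I_inj,

with C = τ_m/R_m. A LIF cell spikes at the first upward crossing of
E_spike, then holds its reset potential (equal to E_rest; the original
report leaves reset unspecified and the M-cells fire at most a few times
per trial, so results are insensitive) for a 2 ms refractory period.

Chemical synapses are single-exponential conductances with instantaneous
rise: a presynaptic spike increments the postsynaptic conductance by
`g_peak` after the axonal delay, and the conductance decays with τ = 2 ms
(both glutamate and glycine). Saturation and short-term plasticity are not
modeled. Glycine reverses at the postsynaptic cell's ECl (−75 mV); the
glutamate reversal is 0 mV (conventional; unreported). Synaptic delays are
rounded to the nearest integration step and the rounding is recorded in
trial metadata.

Gap junctions are unidirectional ohmic drives I = g_gap·(V_pre − V_post)
from afferents onto LIF cells (the HH and LIF formalisms differ, so the
afferent is not back-coupled; whether the original couplings were
bidirectional is unknown). For the afferent→M coupling the presynaptic
voltage is first low-pass filtered with τ = 0.4 ms, standing in for the
lateral-dendrite filtering of the eighth-nerve coupling potential without
a multicompartment M-cell.

### Parameter table

The default configuration (shipped as `data/default_circuit.yaml` and as
`mauthnet.circuit.default_config()`) is: M-cell R_m = 10 MΩ, E_rest = −79,
ECl = −75, E_spike = −61 mV, τ_m = 23 ms; FF R_m = 400 MΩ, E_rest = −77,
τ_m = 10 ms, same ECl and E_spike. Afferent HH densities: g_l = 0.05,
g_Na = 100, g_K = 200 mS/cm² with E_l = −79, E_Na = 50, E_K = −90 mV, and
membrane areas spaced linearly over 2000–20000 µm² (the original spacing
rule is unreported; linear is the simplest gradient with the stated
range). Connectivity per side: FF→ipsilateral M glycine 25 nS (0.3 ms),
FF→contralateral M 2.5× that (stored as the ratio, so overriding the ipsi
value propagates), afferent→M glutamate 12 nS (0.7 ms), afferent→M
electrical coupling 15 nS, afferent→FF electrical 10 nS one-to-one
(each afferent and its FF partner form one functional unit), and — in the
full circuit — FF→contralateral FF glycine 12 nS all-to-all.

**Lumped afferent→M electrical coupling.** The 15 nS afferent→M electrical
conductance is interpreted as the compound conductance of the whole
30-afferent pool (0.5 nS per connection), not 15 nS per afferent. The
per-connection reading places a standing 450 nS load on a cell with a
100 nS leak, which would (i) lower the M-cell's in-circuit input
resistance to ~1.8 MΩ, far from the measured ~10 MΩ, (ii) prevent ±1 nA
holding currents from spanning the IPSP reversal as they do in the
recordings the model reproduces, and (iii) leave the M-cell subthreshold
at every stimulus even with all inhibition removed. The lumped reading
keeps the in-circuit input resistance near 8.7 MΩ and the cell excitable.
The flag (`GapJunctionSpec.lumped`) is per-group and defaults to off; the
one-to-one afferent→FF coupling stays per pair.

### Afferent kinetics and recruitment

The HH afferents use the Traub–Miles rate functions with a threshold-shift
parameter VT. With the stated conductance densities the classic squid
rates cannot place the resting potential at the leak reversal (the
potassium current dominates near rest), whereas the Traub–Miles set has a
well-defined solution: VT is solved numerically (bisection on the
self-consistent resting potential) so that rest sits within 0.005 mV of
the −79 mV target, matching the M-cell as the original model required.
The solved VT ≈ −71.2 mV puts the spike threshold ≈16 mV above rest.
Gates are initialized at their steady state, so an undriven afferent is
exactly stationary.

Stimulus strength is dimensionless. Every afferent on a side receives the
same absolute current `strength × I_unit`, where I_unit is the threshold
current of the smallest cell — so strength 1.0 recruits exactly that cell,
and because channel densities are fixed while total conductance grows with
area, threshold current rises (essentially linearly) with area and the
recruited count is a 30-step non-decreasing function of strength.
Threshold currents are found by vectorized bisection (0.1% relative
tolerance) with the spike criterion "an upward 0 mV crossing within the
probe window"; the window defaults to the drive duration so that
"recruited" and "spikes during the drive" coincide.

The drive waveform is a constant-current step with 5 ms onset and a
default duration of 20 ms. The duration is set by the model's own
calibration target: the balance of excitation and feedforward inhibition
is such that M-cell latencies span roughly 7–20 ms after stimulus onset
(the escape-latency range the model is matched to), and a drive shorter
than those latencies terminates the synaptic barrage before threshold is
reached. The default stimulus grid spans 0 to 4× the full-recruitment
strength: beyond full recruitment, strength continues to raise afferent
firing rates (intensity coding), and the short-latency response regime
lies in that range.

## Numerics

Everything is integrated by exponential Euler at a fixed dt = 0.01 ms
(0.025 ms maximum): for the LIF equation the update is exact between
synaptic events, and for the HH gates and voltage the conductances are
frozen within a step. Plain forward Euler is not used for the HH voltage
because at these densities the voltage relaxation time during the spike
(~9 µs) drops below dt. Gate steady states and decay factors are
tabulated on a 0.005 mV grid and gathered by index, which is what makes
41×41-condition sweeps practical; a sweep integrates all grid conditions
as one batched state. Convergence is guarded by a test that halves dt and
requires spike times to move by less than one step and peak voltages by
less than 0.5%.

Simulations start at the coupled resting fixed point. Because gap
junctions are standing ohmic loads, the FF cells in the full circuit rest
~1.6 mV below their configured E_rest (pulled toward the afferent rest
through the 10 nS pair coupling); the resting-potential invariant is
therefore asserted on isolated populations, and the coupled circuit is
verified to be stationary. Non-finite state raises an error naming the
first offending neuron and time — divergence is never silently recorded.

LIF spike samples are drawn at 0 mV in exported voltage traces (the
integrated state resets immediately); this gives phase-plot analyses a
rising edge to detect, mirroring how spikes present in real recordings.

## Calibration analyses

The trace analyses mirror the experimental procedures: input resistance
interpolates the current family for the −10 mV steady deflection
(steps last 10 τ_m); the membrane time constant is the slowest constant of
a constrained double-exponential fit (multi-start nonlinear least squares
over log-spaced initial constants; a component with negligible amplitude
is ignored, which handles the degenerate single-exponential case); spike
threshold is the voltage at which dV/dt first exceeds 10 mV/ms (the
criterion value is unreported; 10 mV/ms is a common choice and the
estimate is insensitive for LIF traces); and ECl is the zero-amplitude
intercept of the linear fit of IPSP peak amplitude (15 ms window, 1 ms
pre-arrival baseline) against holding potential. For the LIF membrane the
IPSP amplitude is exactly proportional to (ECl − V_hold), so the fit is
linear to machine precision and the intercept recovers ECl essentially
exactly. Calibration protocols isolate the relevant subcircuit by zeroing
the couplings that are not part of the measurement (zeroing a gap junction
also removes its standing load), as an experimenter would characterize
the isolated cell model.

## Choice maps and ablations

A sweep presents every (left, right) strength combination; each M-cell's
first spike inside a 50 ms post-onset observation window (the original
window is unreported) classifies the condition as LEFT_ONLY, RIGHT_ONLY,
BOTH or NEITHER, with latency measured from drive onset. BOTH requires
both cells to fire, regardless of order; if both first cross threshold in
the same step the condition is still BOTH. Region areas are fractions of
grid cells. Initiation shares split exact ties evenly, which keeps the
mirror-symmetric control exactly balanced. Ablations remove cells and all
their connections; half-ablation removes the cells at even pool positions
(deterministic and spread across the recruitment gradient; the original
choice of half is unreported, and a seeded random mode exists for
sensitivity checks).

## Synthetic data and statistics

The statistics stage emulates the study's experimental datasets, whose raw
values are not published. The paired generator draws a log-normal
ipsilateral baseline (bouton counts rounded to integers; IPSP amplitudes
in mV) and multiplies by exp(N(µ, σ²)) for the contralateral value, with
µ = ln 2.44 matching the reported mean contra/ipsi ratio and σ = 0.45
chosen so the sampled ratio range at n ≈ 20 matches the reported
0.97–6.61 span. The behavior generator draws log-normal latencies
(σ_log = 0.45, a heuristic matched to the reported mean/median gaps)
around the reported per-condition medians — e.g. 6 ms lesioned vs 10 ms
unlesioned for FF-ablated fish — and Bernoulli escape directions with the
reported lesioned-side probabilities (0.5 control, 0.25 FF-ablated, 0
M-cell-killed), for 10 fish per condition with 5 latency trials per side
and 10 direction trials per fish.

These generators emulate effect sizes and the per-fish grouping, not the
full structure of real behavioral data: no between-fish variability in the
condition effect, no trial-order or habituation effects, no latency/
direction correlation, and exact log-normality. Passing tests therefore
demonstrate that the analysis pipeline is correct and calibrated at the
study's sample sizes — not that the model generatively reproduces real
fish.

The Wilcoxon signed-rank test uses mid-ranks for ties and drops zero
differences by default (Pratt handling available). The exact null is
computed by convolution over integer-scaled ranks; the two-sided p-value
is the probability of a deviation of W⁺ from its mean at least as large as
observed, which coincides with the doubled-tail definition for the
symmetric tie-free null. The sampled mode uses sign flips with the add-one
estimator; the normal approximation uses the tie-corrected variance
Σr²/4 without continuity correction.

The mixed-model analyses of the original report are deliberately replaced
by fish-level permutation tests with the same grouping structure: the
condition statistic is the mean over fish of a per-fish contrast (median
log-latency difference between sides, or lesioned-side fraction − ½), and
the null is generated by per-fish sign flips (exact enumeration up to 14
fish). Holm's correction (distribution-free) replaces Dunnett's across the
five lesion conditions. For the laterality test the primary p-value is the
pooled exact binomial (exact under the trial-level null, type-I ≈0.040 at
the study's 10×10 structure); the fish-level permutation is reported
alongside and is conservative there (≈0.017) because per-fish fractions
of 10 binary trials are heavily tied. Latencies are compared on the log
scale, making the contrast invariant to rescaling.

## Known limitations

* Single-compartment M-cell; no channel noise; no short-term plasticity;
  auditory drive only (no multimodal afference).
* The afferent rate-function family and the drive waveform are the two
  places where the original specification is silent and the choice
  matters; both are documented above and exposed as parameters.
* Region boundaries of the choice maps are not calibrated to the original
  figures (no printed coordinates exist); only the qualitative orderings
  stated in the text are treated as results.
* The excitatory interneurons of the wider M-cell network are outside the
  modeled motif.
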
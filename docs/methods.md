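# Methods

## Scientific problem

Deep brain stimulation (DBS) of the thalamus suppresses tremor only at
stimulation frequencies above roughly 90 Hz, and loses efficacy again when
the frequency is pushed into the kilohertz range. One mechanistic account —
the "informational lesion" hypothesis — holds that effective DBS masks the
pathological bursting of thalamic neurons and replaces it with regular,
stimulus-locked firing; low frequencies fail because they superimpose on the
bursting, and kilohertz frequencies fail because they evoke irregular firing
and conduction block instead of regular entrainment. This package implements
the simulation study behind that account: populations of model myelinated
axons around a point-source electrode, driven by synthetic thalamic
bursting, stimulated across frequency and amplitude, and scored with a
firing-pattern entropy statistic.

## Axon model

Fibers are double-cable compartmental models of mammalian myelinated axons
(the McIntyre–Richardson–Grill motor-axon model; parameters adopted
verbatim from its published table and shipped in
`src/axondbs/data/mrg_fiber_parameters.json`). The repeating unit between
nodes of Ranvier is node – MYSA (myelin attachment) – FLUT (main paranode)
– 6×STIN (internode) – FLUT – MYSA – node. Each compartment has an
axolemma (capacitance 2 µF/cm²; passive leak in internodal sections) facing
a periaxonal space beneath the myelin sheath, which is itself a
capacitive/resistive layer to the extracellular medium — two coupled
longitudinal cables. Nodes carry fast Na⁺ (3.0 S/cm², m³h), persistent Na⁺
(0.01 S/cm², p³), slow K⁺ (0.08 S/cm², s) and leak (0.007 S/cm²)
conductances with the published rate functions at 36 °C. Supported
diameters: 5.7 µm (default; internodal spacing 500 µm), 10 µm, 15 µm.

The resting potential is −80 mV; gates are initialized at their steady
state and every simulation is preceded by a 20 ms settle period, after
which the state drifts by less than ~0.05 mV over 100 ms. The model
reproduces the expected excitability phenomenology: conduction velocity
≈ 32 m/s at 5.7 µm with < 5 % dispersion of internodal delays, an absolute
refractory period just under 1 ms followed by a supernormal phase (a known
feature of this axon model's recovery cycle, driven by the depolarizing
afterpotential of the passive internode), and extracellular thresholds that
grow with electrode distance and shrink with fiber diameter.

## Stochastic channel gating

Nodal fast Na⁺ and slow K⁺ channels can be simulated as finite populations
of Markov channels: the canonical 8-state m³h scheme for Na⁺ and the
2-state s gate for K⁺, with transition rates tied to the deterministic
α/β functions so the deterministic model is the exact large-N limit. The
K⁺ count follows N_K = round(N_Na·18/60); single-channel conductances are
nodal maximum ÷ channel count, keeping nodal maxima identical across
variants. The persistent Na⁺ conductance is always deterministic.

Transitions are sampled per time step with competing-risk binomials
(exit probability 1 − e^(−RΔt), leavers split multinomially among
destinations). Steps are subdivided automatically so the fastest exit rate
among *occupied* states satisfies RΔt ≤ 0.5, keeping the
one-jump-per-substep approximation accurate; a step that would need more
than 10⁵ substeps raises an error rather than degrade silently.
Large-count draws (variance > 100) use the Gaussian approximation of the
binomial, as in tau-leaping; the relative error is O(1/√var) and
negligible at those counts. Channel totals are conserved exactly as an
integer identity at every step.

At 200 Na⁺ channels per node, channel noise occasionally fires the fiber
spontaneously within 1 s; at 10,000 channels per node it does not —
reproducing the qualitative separation between low- and high-density
stochastic variants.

## Stimulation field and waveforms

The electrode is a monopolar point source in an infinite homogeneous
isotropic medium of resistivity 500 Ω·cm (quasi-static): φ = ρI/(4πr),
i.e. 397.9 mV at 1 mm per 1 mA. Waveforms are trains of 90 µs monophasic
cathodic rectangular pulses (amplitudes quoted as positive mA, delivered
negative) or zero-phase peak-amplitude sinusoids. For integration, the
waveform is averaged over each time step (charge-exact), so a 90 µs pulse
deposits exactly its charge even at the 0.02 ms step.

## Population geometry

Fibers run parallel to each other; the electrode shaft extends
perpendicular to the fiber plane. Axis positions are sampled uniformly
over the disk of radius 3 mm around the source, excluding the 0.635 mm
sphere around the source and the semi-infinite cylinder of the same radius
above it (the shaft of a 1.27 mm DBS lead) — a U-shaped allowed region.
The node lattice is shifted longitudinally by a uniform offset within
±half an internodal spacing, and the node nearest the electrode is the
40th from the distal end. Quiescent fibers have 81 nodes (4 cm); bursting
fibers have 171 nodes (8.5 cm) so that intrinsic activity injected at the
proximal end interacts realistically with stimulus-evoked activity before
reaching the electrode, 6.5 cm away.

## Synthetic intrinsic bursting

The intrinsic drive emulates pathological thalamic bursting: burst onsets
form a regular renewal process at a per-fiber rate drawn from
Normal(4.33, 0.06) Hz; each burst contains a uniform 3–8 spikes at a
constant intra-burst interval set by the fiber's intra-burst rate, drawn
once per fiber from Normal(243.40, 89.09) Hz (truncated above 20 Hz). The
first onset is uniform within one period, desynchronizing fibers. Two
free choices are fixed by calibrating the drive's entropy against the
~1.49 bits/spike of the intrinsic pattern it emulates. First, the
placement of the intra-burst variability: with per-fiber draws the raw
joint ISI-pair entropy is ~1.5 bits/spike; per-burst or per-interval
draws give 5.2 and 7.0 bits/spike under any normalization and are
excluded. Second, the unpublished spikes-per-burst range: uniform 3–8
yields 1.52 ± 0.20 bits/spike (3–7 gives 1.56, 4–7 gives 1.42), so 3–8
is the default. The
generated trains are delivered by intracellular current pulses (0.1 ms,
2× the fiber's intracellular rheobase) at the proximal node, each of which
elicits exactly one propagating spike in an unstimulated fiber.

What the generator does *not* model: the detailed spike timing of a
thalamocortical relay neuron (burst accelerando/decelerando, calcium-spike
dynamics), within-fiber drift of burst statistics, and any feedback from
stimulation onto burst generation. Tests passing against this drive show
that the axon and analysis chain behave correctly for a drive with the
published first-order statistics, not that thalamic spike timing is
reproduced in detail.

## Numerical integration

The coupled double-cable system is advanced with backward Euler at a fixed
step (0.02 ms workhorse, 0.002 ms fine; 0.005 ms for
kilohertz-stimulation population runs). Per step, nodal gates advance
first by exact-exponential (Rush–Larsen) relaxation — or by the stochastic
Markov update — at the previous potential (staggered scheme); the linear
system in the intracellular and periaxonal potentials is then assembled as
a block-tridiagonal matrix with 2×2 blocks and solved by block Thomas
elimination (the system is diagonally dominant; no pivoting). At nodes the
periaxonal space opens to the extracellular medium through a large shunt
conductance. Gate-rate evaluation clamps the potential to [−250, 150] mV
purely to avoid exponential overflow under extreme stimulus artifacts; all
gates are saturated beyond that range. Divergence (non-finite state)
raises immediately.

Accuracy: against the closed-form RC response of a single passive
compartment the scheme shows first-order O(Δt) error. The coarse 0.02 ms
step reproduces spike counts and initiation timing (< 0.1 ms error near
the initiation site) but slows conduction by roughly 30 % and raises
extracellular thresholds by ~15 %; threshold- and timing-sensitive
quantities (recruitment calibration, conduction velocity) therefore use
the 0.002 ms step, and kilohertz population runs use 0.005 ms, the
coarsest step at which near-electrode fibers still follow sub-kHz trains
one-for-one.

## Spike detection, activation, and conduction block

Spikes are upward crossings of −20 mV at the distal node with a 1 ms
refractory rule. A fiber counts as *activated* by a test train when at
least 90 % of the pulses in a 100 ms, 100 Hz train are answered by
propagated spikes. Activation and block thresholds are found by bisection
(1–2 % relative tolerance) with the upper bracket located by doubling,
because far-suprathreshold stimuli can block rather than excite (and very
strong kilohertz stimuli can re-excite distant nodes), making the
activated/blocked predicates non-monotonic at fixed brackets.

Conduction block of intrinsically driven fibers is classified from the
distal output after excluding the first 100 ms (the onset transient, in
which fibers headed for block typically still emit at least one propagated
spike): *blocked* if no distal spikes occur despite intrinsic drive,
*partial* if fewer than half of the intended spikes appear, *conducting*
otherwise. The one-half partial cutoff is a package choice, recorded here
because no published value exists.

## Firing-pattern entropy

Regularity is measured as the Shannon entropy of the empirical joint
distribution of consecutive ISI pairs (ISIₙ, ISIₙ₊₁) on logarithmic bins,
bin_k = bin₀·10^(k/κ) with bin₀ = 0.4 ms and κ = 20 bins per decade
(the exponent is written k/κ: only this orientation yields κ bins per
decade). The entropy is reported raw in bits/spike — the convention under
which the intrinsic bursting drive lands at its published ~1.49 value — and
is zero exactly when one pair bin is occupied (perfectly regular firing).
Fibers with fewer than three spikes have *undefined* entropy and are
classified by drive/block status, never as regular by default. The
regular/irregular cut-off is 1.0 bit/spike; blocked fibers are excluded
from "regular" but retained in denominators when computing the fraction of
regularized fibers.

## Emergent study-level behavior

With these components the package reproduces the study's mechanism:
90 µs cathodic pulse trains at 100 Hz and 1.6 mA recruit roughly
70–75 % of a randomly placed 100-fiber population; 20 Hz stimulation
superimposes on the bursting and raises entropy; 130–1000 Hz masks the
bursting (collision of antidromic stimulus spikes with intrinsic spikes
plus refractory occlusion at the injection site) and gives the entropy
minimum; 2 kHz produces irregular, variable-latency firing with the
kilohertz-regime entropy maximum; and ≥ 4 kHz produces conduction block
whose fraction grows with amplitude and frequency, lowering entropy again.
Masking in this implementation is strong but not total at 130 Hz: because
intra-burst spikes run at ~243 Hz, individual burst spikes can slip
through the 130 Hz antidromic collision stream over the 6.5 cm proximal
segment, leaving residual entropies of ~0.5–1.5 bits/spike rather than
exactly zero; at ≥ 200 Hz (stimulus period shorter than twice the
proximal transit time) the collision corridor closes and masking becomes
essentially complete. Block thresholds for cathodic pulse trains decrease
with frequency above ~3 kHz while sinusoidal block thresholds increase —
the waveform inversion reported for these stimuli.

## Problem sizes and defaults

Desk-scale presets use 8–25 fibers, 0.7–1 s epochs and coarse
frequency/amplitude grids; the full-scale study design (100 fibers, dense
grids) is reachable through the same `ExperimentSpec` fields. Recruitment
calibration uses 100 fibers at the fine step. These sizes were chosen so
that population fractions carry ~±10 % sampling error, which is the same
order as the across-seed variability of the quantities they estimate;
fiber count sharpens recruitment fractions but does not change mechanisms.

## Known limitations

- Straight, parallel fibers only; no curved trajectories, no other neural
  elements (somas, dendrites, synapses).
- No periaxonal potassium accumulation, which contributes an additional
  block mechanism at high frequencies in real axons.
- The burst generator reproduces first-order burst statistics, not
  thalamocortical spike timing.
- The coarse step's conduction slowdown makes absolute spike latencies at
  the distal node step-dependent; analyses here depend on counts and
  patterns, not absolute latency.
- Entropy estimates from 1 s epochs are noisy (few hundred pairs); the
  1 s vs 4 s comparison bounds the induced error at < 0.5 bits/spike for
  driven fibers.
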
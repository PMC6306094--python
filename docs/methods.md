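# Methods

## Model structure

The simulator implements a feed-forward cascade of five networks with
one recurrent element (lateral inhibition inside the antennal lobe):

- **RN** — one receptor-neuron signal per glomerulus (60 by default),
  driven by a glomerulus-specific spontaneous rate plus odor input,
  inhibited by LNs.
- **LN** — one lateral-neuron signal per glomerulus, excited by the
  local RN, inhibiting RNs, LNs and PNs across glomeruli with class
  weights in the ratio 6:2:1 (LN→RN : LN→LN : LN→PN).
- **PN** — one excitatory projection-neuron signal per glomerulus
  (standing in for the ~5 biological PNs that carry the same signal),
  excited by the local RN, inhibited by LNs.
- **QN** — 15 multi-glomerular inhibitory projection neurons, each
  pooling a random third of the glomeruli.
- **KC** — 2000 Kenyon cells, each excited by exactly 10 randomly
  chosen PNs, inhibited by the QNs and by a constant lateral-horn
  damping term `L0`.
- **EN** — a single extrinsic readout neuron summing all KCs.

All populations obey `τ dx/dt = −x + s(x̃)` with a shared decay
constant and a shared saturating nonlinearity
`s(x) = F_max · tanh(slope · max(x, 0) / F_max)`. This form is
bounded, monotone, has unit slope at the origin and `s(0) = 0`, so a
population with no drive sits exactly at zero rate — which is what
makes KC silence at rest a structural property rather than a tuned
one. Additive white noise of intensity ε enters the four AL
populations only, so KC and EN trajectories are deterministic
functions of the AL trajectory. Rates are clipped at zero after every
step (the stochastic update can undershoot; the continuous-time system
cannot).

Octopamine enters as a time-varying amplitude `a(t)` (raised-cosine
per episode) multiplying excitation by `(1 + a·M^O)` and inhibition by
`(1 − γ_inh·a·M^O)` per population, with diagonal channel matrices
drawn for RNs and LNs and fixed at zero for PNs (and absent for
KC/EN). The binary Hebbian gate `o(t)` is a separate channel: it is 1
only during training episodes, so a control-octopamine period
stimulates the AL without inducing plasticity.

## Connectome generation

Connection weights are Gaussian with standard deviation proportional
to the class mean (`σ = v·μ`, `v = 0.3`), clipped at zero — negative
draws would otherwise flip the sign conventions of the dynamics.
AL-internal inhibitory matrices are produced in two stages: a shared
glomerulus-to-glomerulus arborization matrix (unit mean, zero
diagonal) is scaled by a type-specific mean and perturbed
entry-by-entry. The composition is multiplicative, which reproduces
both correlation structures the architecture implies: weights onto
different neuron types within one glomerulus correlate (shared
arborization factor), and weights within one type share their class
scale. A separate per-glomerulus GABA-sensitivity factor (unit mean)
rescales LN→PN rows only. RN spontaneous rates are
`bias + Gamma(shape, rate)` draws, giving the long-tailed order-of-
magnitude spread between glomeruli that the raw-rate measure `M(t)`
exists to normalize away.

## Calibrated defaults

Per-class connection means are not constrained individually by data;
they were calibrated jointly, once, so the default template reproduces
the circuit's qualitative operating regime:

| parameter | value | role |
| --- | --- | --- |
| τ | 0.5 s | shared decay; pulse responses decay over ~1–2 s |
| ε (`noise`) | 3.0 | AL noise; PN spontaneous σ/μ ≈ 0.3–0.7 |
| `sigmoid_max` | 180 spikes/s | firing-rate ceiling |
| `mu_lr : mu_ll : mu_lp` | 0.030 : 0.010 : 0.005 | 6:2:1 lateral inhibition |
| `mu_pk`, `mu_qk` | 0.5, 0.15 | KC drive scale |
| `mu_ke` | 0.02 | naive EN odor responses of a few spikes/s |
| `lh_inhibition` | 30 | ~5–25% of KCs respond to an odor; rest silent |
| `mu_octo_rn`, `mu_octo_ln` | 0.6, 0.4 | AL activity shifts visibly under octopamine while KCs alone stay silent |
| `odor_strength` | 800 | strong, partially saturating RN drive per hit glomerulus |
| `gamma_pk`, `gamma_qk`, `gamma_ke` | 5e-6, 8e-6, 1e-6 | 5–20 reinforced stimulations give a 30–100% EN gain on the trained odor |
| `rn_spont` (shape, rate, bias) | 1.5, 0.3, 0.5 | spontaneous PN rates spanning ~0.5–15 spikes/s |

The decay constant is a deliberate compromise: a faster τ tracks the
0.2 s odor pulses more sharply, but first-order integration of those
fast transients at Δt = 10 ms then deviates further from a
Runge–Kutta reference, and the deviation compounds down the cascade
(each stage integrates the previous stage's already-lagged output;
the readout neuron additionally sums thousands of correlated
Kenyon-cell lags, so its relative error equals the mean relative KC
error regardless of the readout gain). At τ = 0.5 s the maximal
discrepancy on a full-size moth is about 2% of the peak rate,
concentrated in the pulse-onset transients; between pulses and at
steady state the paths agree closely, and halving Δt halves the
deviation, as expected for a first-order scheme. Pushing the
deviation below 1% would require τ ≳ 1.5 s, at which point responses
no longer return to baseline within the 4 s inter-stimulation gaps —
so τ = 0.5 s stands, with rates returning to their spontaneous
envelope within ~2 s of pulse offset.

Training uses one octopamine episode spanning each training block
rather than per-stimulation injections. With per-pulse injections the
octopamine transient arrives before the slower lateral-inhibition loop
has settled, transiently disinhibiting the mushroom body and
recruiting Kenyon cells that have nothing to do with the trained odor;
growth then generalizes to control odors. With a sustained episode the
AL reaches its octopamine-elevated balance first, and the KC set
active during the stimulations stays odor-specific. The Hebbian growth
rates are small enough that octopamine alone (in the gaps between
stimulations) drives no appreciable growth, because the KCs are then
essentially silent — the AND-gate property of the Hebbian rule doing
its noise-filtering job.

## Stimuli and schedules

Odor pulses are raised-cosine (Hamming) windows, 0.2 s by default,
separated by 4 s gaps; their smooth edges keep the discretized system
accurate at Δt = 10 ms. An odor map assigns each odor 20 of 60
glomeruli uniformly at random with Gaussian stimulation weights; with
four odors this yields on average ~6 glomeruli unique to an odor and
~14 shared. The canonical learning schedule is: settle; 16
stimulations per odor (naive response); a 10 s control-octopamine
period (gate closed); training sessions of 5 stimulations each with
octopamine and the gate open; rest; 16 post-training stimulations per
odor.

## Plasticity

`Δw_ab = γ·f_a·f_b·Δt` applied every timestep while the gate is open,
which makes the accumulated growth independent of the step size.
Structural zeros of the PN→KC mask never grow: training changes
strengths, not wiring. There is no weight ceiling and, by default, no
decay; runaway KC excitation is braked by growth of the inhibitory
QN→KC layer, which is why the model carries 15 QNs rather than the
handful reported anatomically. An optional exponential decay flag
exists on `PlasticState` for experiments that want unused connections
to fade.

## Firing-rate measure

`M(t) = (F(t) − μ̄_S(t)) / σ_S(t)` expresses a rate as the distance
from the smoothed spontaneous mean in units of the locally windowed
spontaneous standard deviation. `μ_S` is a centered moving average of
the spontaneous samples; `μ̄_S` a quadratic fit of it over time (it
absorbs slow drifts, e.g. under octopamine); `σ_S(t)` the standard
deviation of the residuals within a 10 s moving window. Neurons whose
mean spontaneous rate is below 1 spike/s are excluded — the Gaussian
envelope assumption fails there. On stationary Gaussian input the
measure is standard normal, and it is invariant under affine
rescaling of a neuron's rate series. A response is displayed as
excited/inhibited outside ±2.5, with ±2 used for "strong response"
statistics. KCs are classified active/silent at 1 spike/s.

## Experiments

The **learning battery** runs the canonical schedule for every
{trained odor, session count, noise realization} triple on a single
moth (defaults: 4 odors × 4 session counts × 11 realizations = 176
runs; the scaled-down acceptance variant uses 2 odors × {1, 2}
sessions × 11). Realizations share the moth, odor maps and schedule
and differ only in the SDE noise stream; per-run seeds are derived by
counter so results are independent of execution order. Each run
yields per-odor naive and post-training EN responses (mean rate in the
pulse window plus a 0.3 s tail) and their percent change; a one-way
ANOVA compares trained versus control percent changes. Batteries are
run on moths whose naive EN responses are within 3× of each other
(`find_even_moth` probes candidate seeds with a short baseline-only
schedule), because percent-change comparisons across odors are
scale-confounded otherwise.

The **sparsity sweep** varies the lateral-horn damping over
(16, 22, 28, 36, 48, 70), spanning >40% of KCs active down to <1%,
training one of two odors with 15 stimulations per level. Reported
per level: mean percent of KCs responding to an odor (naive), the EN
response signal-to-noise ratio `SNR = μ(f)/σ(f)` over naive responses,
and the learning focus `μ(f_T)/μ(f_C)` over post-training responses,
plus cubic fits of both against percent-active. Dense coding gives
reliable responses but unfocused learning (at the dense end both
post-training responses saturate and the focus ratio collapses to 1);
sparse coding focuses learning but degrades reliability; both hold up
in the ~5–15% band.

## Numerical choices

- Euler–Maruyama with the noise term `ε·√Δt·N(0,1)` per AL coordinate;
  Δt = 10 ms.
- `check_convergence` compares the noise-free Euler path against
  classic 4th-order Runge–Kutta with sub-steps aligned to the
  schedule grid, both integrating the identical right-hand side (the
  stimulus held constant over each timestep). Comparing against a
  differently sampled stimulus would conflate signal discretization
  with integrator error.
- Degenerate inputs: a spontaneous segment with (near-)zero variance
  falls back to unit σ so that `M` stays finite; an SNR over constant
  responses is NaN; a learning focus with zero control response is
  +inf.
- The fused integration loop in `simulate` is algebraically identical
  to composing `drift` and `step_em`; a test asserts the equivalence.

## What the synthetic generator does and does not emulate

Generated moths reproduce the architecture's statistical skeleton:
glomerular correlation structure, sparse random PN→KC wiring, uniform
naive KC→EN weights, gamma-distributed spontaneous input, and additive
AL noise. They do not emulate receptor-level odor chemistry (odor maps
are random, not ligand-based), pheromone processing, non-olfactory KC
input, spike timing, oscillations, or the scale-free weight
distributions older moths may develop. Passing tests therefore
demonstrate the circuit-level learning mechanism under the model's
own assumptions, not a fit to any particular animal's recordings.

## Known limitations

- One EN; behavioral action thresholds are reported as overlays only.
- The AL octopamine response is calibrated qualitatively (direction
  and rough magnitude), not against electrode data.
- The learning-focus ratio compares raw post-training responses, so it
  is only interpretable on moths with roughly even naive responses;
  the sweep selects such a moth by construction.
- Long training (≫20 reinforced stimulations) eventually saturates
  the EN at the rate ceiling, after which focus measures degenerate
  toward 1.
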
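# Methods

`precistim` emulates a vibrotactile two-interval discrimination study end to
end: stimulus synthesis, adaptive difficulty titration, a precision-weighted
ideal observer, and a seven-model nonlinear dynamic-causal-modeling (DCM)
analysis of synthetic four-region BOLD data with random-effects Bayesian
model selection (RFX BMS). This note records the models, the parameters
that matter, the numerical choices, and what the synthetic data do and do
not establish.

## Stimuli

A flutter stimulus is a unit-amplitude sinusoid (10–50 Hz; base 34 Hz,
default duration 512 ms, default sample rate 8 kHz). "Noisy" stimuli are
synthesized cycle by cycle: cycle *k* has period
T_k = T_base + ε_k, ε_k ~ N(0, (γ·T_base)²), with jitter fraction γ = 0.08
by default, so the population SD of the cycle periods equals 8% of the base
period (2 ms at 40 Hz). Each cycle is one complete sine period, so the
waveform is continuous at cycle boundaries; the final partial cycle is
truncated at the requested duration and excluded from the stored period
list. Jitter acts on the *period*: the mean period is preserved exactly,
while the mean instantaneous frequency slightly exceeds the nominal
frequency (Jensen's inequality). This is a property of the generative
definition, not an artifact, and is left uncorrected. Non-positive period
draws are rejected and redrawn — a ≈12.5σ event at 8% jitter, but the
generator must be total for any fraction. Period SD uses the
divide-by-N (population) convention because it describes the realized cycle
ensemble within one vibration, not an estimator of a parent distribution.

## Staircase titration

Two interleaved multiplicative staircases (10% steps, initial Δf = 5 Hz)
adjust the frequency difference between the 34 Hz base and a comparison
stimulus. Every error steps Δf up; a step-down occurs after *m*
non-consecutive correct responses (*m* = 6 easy, *m* = 2 hard), with the
correct-response tally persisting through errors and resetting only on a
step-down. Balancing expected up- and down-steps per trial,
(1 − p) = p/m, gives the equilibrium accuracy p* = m/(m+1): 2/3 for the
hard track and 6/7 ≈ 0.857 for the easy track. Note that 6/7 is what the
six-down rule can deliver; a ~90% target for that rule is an aspiration
rounded upward. Simulated asymptotic accuracy sits slightly (~1–2 points)
below p* because the staircase oscillates around the equilibrium difficulty
and the psychometric function is concave there; the acceptance tolerance
accounts for this.

Track selection per trial is uniform 50/50. Converged deltas are estimated
as the geometric mean of Δf over the final third of each track (the
multiplicative dynamics make log-Δf, not Δf, the natural averaging scale);
the medium difficulty is the geometric mean of the two converged deltas.
Runs shorter than 50 trials are flagged unconverged. No floor or ceiling is
imposed on Δf beyond positivity. The simulated observer's probability of a
correct faster-slower response is Φ(Δf / (σ√2)) — the ideal two-interval
comparison of percepts with encoding noise σ (default 1.5 Hz in the
titration runs; σ only shifts the converged Δf, not the equilibrium
accuracy).

## Observer model

Each stimulus is encoded as a Gaussian percept with mean f + bias and
standard deviation √(σ_p² + κ²s²), where σ_p is internal encoding noise
(default 1 Hz), κ (default 1) couples stimulus roughness to percept noise,
and s is the roughness expressed in frequency units. Because a frequency
estimate effectively averages the ~f·T cycles present, s = γ·f/√(f·T)
(≈ 0.65 Hz for the standard noisy 34 Hz stimulus). The observer knows its
own uncertainty: the percept carries its SD ("known_sd").

Decisions:

- faster-slower: respond on the sign of the percept difference (ties by
  fair coin). Accuracy is criterion-free.
- same-different (precision-weighted rule, default): respond "different"
  iff |v₂ − v₁| / √(sd₁² + sd₂²) > c (default c = 1, in z units); boundary
  equality resolves conservatively to "same".
- same-different (raw-difference rule): |v₂ − v₁| > c with c in Hz, used as
  the contrast model that lacks precision weighting. When the two rules are
  compared "at matched parameters", the raw criterion is set to
  c·σ_p·√2 — the value at which both rules make identical decisions on
  regular same trials — so the comparison isolates the precision weighting
  itself.

On same-noisy trials both stimuli reuse the identical jitter sequence, so
the roughness contribution to the two percepts is a single common draw that
cancels from their difference; internal noise remains independent, and the
believed SD still includes the roughness term (the observer knows the
stimulus feels rough, not its exact sequence). This asymmetry — the
denominator grows with roughness while the same-trial numerator does not —
produces the signature crossover: noise *raises* same-trial accuracy and
*lowers* different-trial accuracy under the precision-weighted rule, and
does neither under the raw rule. Sensitivity is summarized by
d′ = z(hit) − z(false alarm) with rates of exactly 0 or 1 corrected to
1/(2N) and 1 − 1/(2N). Reaction times are not modeled; the trial table's RT
column is a placeholder.

## Event schedules

Trials follow the study clock: 512 ms stimuli, 600 ms inter-stimulus
interval (second-stimulus onset at 1112 ms), a 2 s response window from
second-stimulus onset, and inter-trial intervals uniform on [6, 12] s,
defined as the gap from second-stimulus offset to the next trial onset (the
source timing names only the range). Same-different sessions contain
exactly half same pairs — an even trial count is required — crossed with
the regular/noisy factor as evenly as possible. A canonical double-gamma
HRF (g(t;6,1) − g(t;16,1)/6, kernel integral 5/6) and a convolution utility
support decision-locked evoked-response checks (e.g. a 200 ms pre-response
boxcar regressor).

## DCM generative model

Four regions — IPL, rPFC, DLPFC, SFG — with one neural state each:

dx/dt = (A + Σ_j u_j B⁽ʲ⁾ + Σ_k x_k D⁽ᵏ⁾) x + C u

Self-connections are −0.5·exp(θ_self,i), strictly negative by construction.
Inputs are boxcars: u_stim over both stimulus epochs, u_regular and
u_different spanning trials of the corresponding condition/truth. All seven
motifs share a common base (stim → IPL; IPL→rPFC modulated by regular;
IPL→DLPFC modulated by different; backward DLPFC→IPL) and differ in how
activity reaches SFG: Diamond (serial via both rPFC and DLPFC), Fork
(direct IPL→SFG modulated by both conditions), Legs 1/2 (one prefrontal
afferent modulated by one condition), and Stork 1/2/3 where one prefrontal
region gates the other's afferent to SFG through D (Stork 3 has both
gates). The edge lists live in `data/model_space.json`; alternative
readings of the motifs are a data edit, not a code change.

Hemodynamics are the standard balloon model per region (signal decay
κ_h = 0.64 s⁻¹, feedback γ = 0.32 s⁻¹, transit time τ = 2 s, stiffness
α = 0.32, resting extraction E₀ = 0.4, resting volume V₀ = 0.04), with
BOLD = V₀(k₁(1−q) + k₂(1−q/v) + k₃(1−v)), k₁ = 7E₀, k₂ = 2, k₃ = 2E₀−0.2.
Integration is fixed-step RK4 with inputs held constant over each step
(they are boxcars on the same grid), compiled with numba and batched over
parameter sets; the dt/10 refinement of the same input stream is the
reference oracle. Default grid 10 ms; group-recovery runs use 50 ms, still
two orders of magnitude below the fastest hemodynamic time constant, which
a refinement check confirms is inside the integrator tolerance. Divergence
(non-finite or |x| > 10³, or v, q leaving the positive domain) raises an
error naming the failure time during simulation and rejects the step
during fitting.

### Generating parameters

The synthetic group's group-mean parameters are chosen to express the
study's logic: weak unconditional forward couplings from IPL (0.1 s⁻¹)
with strong condition-specific modulations (B = 1.0 s⁻¹), so rPFC responds
mainly on regular trials and DLPFC mainly on different trials; afferents to
SFG 0.3 s⁻¹; backward DLPFC→IPL −0.2 s⁻¹; driving input 0.8; gates
D = 1.5 s⁻¹ per unit state, which roughly doubles the gated afferent at
peak gating-region activity (~0.25). Under gating, SFG then expresses a
regular-by-different *product* response that no bilinear motif can
reproduce — the condition that makes the nonlinear motifs empirically
distinguishable at all. Between-subject variation is Gaussian (SD 0.1) on
every nonzero A/B/C/D entry, with unstable draws resampled;
self-connections and hemodynamics are fixed across subjects. Observation
noise is white Gaussian with SD equal to the across-region mean temporal SD
of the noise-free BOLD divided by the configured SNR (an AR(1) option
exists). All randomness descends from the master seed through a
SeedSequence tree, so any subject is reproducible from (master seed,
subject index).

## Inversion

Each model is inverted by MAP estimation: Levenberg-damped Gauss-Newton on
the Gaussian log-joint, with a batched forward-difference Jacobian
(step 10⁻³) and EM updates of per-region noise precision under a weak
Gamma(10⁻³, 10⁻³) hyperprior. Priors: A/B/C ~ N(0, 0.25),
D ~ N(0, 0.0625) (tighter, reflecting their weak identifiability),
θ_self ~ N(0, 0.0625), and one shared log-transit-time deviation
~ N(0, 0.0256) as the only free hemodynamic parameter. The posterior
covariance is the Laplace inverse-curvature at the optimum (symmetrized,
ridge-repaired with a warning if needed), and the free energy is

F = log p(y|θ̂) − ½[(θ̂−μ₀)ᵀΠ₀(θ̂−μ₀) + ln det Σ₀ − ln det Σ],

validated to 10⁻³ nats against the conjugate closed-form evidence on a
linear-Gaussian problem. Convergence is |ΔF| < 10⁻⁴ on three successive
iterations or the iteration cap; a capped fit is returned flagged, not
raised. Seeded restarts (default 3; 2 in the group-recovery configuration)
from jittered initializations guard against local optima, keeping the
best-F solution. An iteration cap of 0 returns the prior as posterior.
This is a deliberately simple, fully reproducible approximation of the
variational objective; a full variational-Laplace scheme is a possible
extension, and no numerical agreement with any existing DCM package is
claimed or sought.

A practical identifiability note: the *mean* effect of a gate trades off
against its target A entry, so posterior D values shrink toward the prior
while the condition-dependent component — which the bilinear motifs cannot
absorb — carries the model comparison. Parameter-recovery calibration is
therefore gated on A and B (≥ 80% of generating values inside 90% credible
intervals at SNR 1); D recovery is reported, not gated.

## Model selection

RFX BMS follows the variational Dirichlet scheme: responsibilities
g_nk ∝ exp(F_nk + ψ(α_k) − ψ(Σα)), α = α₀ + Σ_n g_n (α₀ = 1), iterated to
|Δα| < 10⁻⁴. Exceedance probabilities are Monte-Carlo estimates from 10⁶
Dirichlet draws (sampling rather than closed form, since K = 7); the K = 2
case is checked against Beta-comparison quadrature.

## Study-scale choices

The canonical recovery conditions (`recovery_conditions()`) are 8 subjects,
~6-minute sessions (≈32 trials at TR 2 s, ~180 volumes), SNR 1,
between-subject SD 0.1, and generation/fitting on the 50 ms grid — a
desk-scale study in which both the Stork 3 and the Fork generators are
correctly recovered by exceedance probability, and which the acceptance
tests rerun from scratch. The behavioral analyses use 8,000–12,000
simulated trials per context so the crossover contrasts carry ~1-point
Monte-Carlo error. Exceedance magnitudes and posterior parameter values
are treated as ordinal evidence (winner identity), not numeric targets.

## What the synthetic data do not show

The generator emulates trial timing, stimulus statistics, design balance,
and a known ground-truth DCM with white observation noise. It does not
emulate human lapses, learning, criterion drift, serial dependencies,
physiological/motion noise, spatial (voxel-level) structure, ROI
extraction, or session breaks (one continuous run by default; a
multi-session split is a configuration choice). Passing tests therefore
establish internal validity — the chain recovers what it generated under
realistic sizes and noise — not that human data would yield the same
parameter values; empirical human effect magnitudes (F statistics, human
d′ values, imaging cluster statistics) are out of scope by design. Model recovery is demonstrated for the two generators above at
fixed seeds, not as a guarantee for every seed or every corner of the
parameter space.
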
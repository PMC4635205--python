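# Methods

`behaviordyn` models the spread of a behavior (the running example is exam
stress propagating through a student population) at four levels —
aggregate rate equations, random-graph percolation, degree-based mean
field, and explicit networked agents — and calibrates the aggregate
model's two free propensities from psychophysiological measurements via a
stress-threshold rule. This note records the models, the parameter
conventions, the numerical choices, and the places where the design was
genuinely open.

## Aggregate diffusion models

**Difference equation.** The adopted fraction evolves as
`S(t) = S(t-1) + α(1−S(t-1)) + β(1−S(t-1))S(t-1)`, with α the rate of
spontaneous/environmental behavior contraction and β the rate of
contraction by social imitation (both per unit time, ≥ 0). The raw
recurrence can overshoot 1 when α+β is large; because S is a fraction,
each step is clipped to [0, 1]. The continuous limit is
`dS/dt = (α + βS)(1 − S)`, with closed form
`S(t) = (1 − e^{−(α+β)t}) / (1 + (β/α) e^{−(α+β)t})` for S(0) = 0.
The closed form requires α > 0 and we reject α = 0 rather than evaluate
the limit; trajectories from a general S(0) go through the ODE/recurrence
path instead.

**Stock-and-flow adoption model.** In counts: PotentialAdopters P and
Adopters A = N − P, with flows
`AdoptionFromImitation = P · ImitationEffectiveness` and
`AdoptionFromWOM = A · P · ContactRate · AdoptionFraction / N`, and
`dP/dt = −(AdoptionFromImitation + AdoptionFromWOM)`. Note the naming
convention is kept exactly as in the system-dynamics formulation this
implements, even though the roles mirror the Bass model's
innovation/imitation terms inversely (the "imitation" flow is the
contact-free channel; the word-of-mouth flow carries the contact term).
Per capita this model reduces to the continuous difference-equation with
α = ImitationEffectiveness and β = ContactRate · AdoptionFraction, which
is verified in the tests. Counts are the primary output; the
`sd_trajectory_to_adoption` helper converts to fractions.

**SIR.** Standard Kermack–McKendrick compartments in fractions, with
`InfectionRate = c·i·S·I/N` and `RecoveryRate = I/D` (contact rate c,
infectivity i, mean behavior duration D); a normalized parameterization
(transmission rate ρ = c·i, recovery rate 1/D) is also accepted.

**Integration.** All ODEs use adaptive explicit Runge–Kutta
(`scipy.integrate.solve_ivp`, RK45) with fixed output sampling; the models
are non-stiff over the parameter ranges of interest. Tolerances default to
rtol 1e-9/1e-10, tight enough that conservation (P + A = N, S + I + R = 1)
holds to 1e-8 and the half-adoption time is stable to well under 1%
against a 100×-finer reference.

`time_to_adoption` reports the first crossing of a level by linear
interpolation between output samples, and is absent (None) when the level
is never reached.

## Network models

**Generators.** Poisson (Erdős–Rényi) graphs, preferential-attachment
trees (one edge per arriving node, attachment probability ∝ degree, giving
a power-law degree tail with exponent in [2, 3]), and the configuration
model by stub matching. Configuration-model self-loops and multi-edges are
removed after matching — standard practice; the degree distortion is O(1)
edges at the sizes used. Graphs are `networkx.Graph` objects throughout.

**Immunity and percolation.** Each individual is immune to behavioral
influence with probability α and removed from the graph. On the residual
network of m = (1−α)n nodes, a giant component emerges at p·(1−α)·n = 1;
above it, the expected outbreak fraction r among susceptibles solves
`r = 1 − e^{−c r}` with c = (1−α)np (we solve it by bracketed Brent root
finding to near machine precision; the inverse relation c = −ln(1−r)/r is
also exposed). For p > ln(m)/m the residual network is connected
asymptotically; `connectivity_regime` classifies p against both bounds.
For arbitrary degree sequences the configuration-model threshold is
⟨d²⟩ = 2⟨d⟩, reported as a signed margin; when immune removal applies we
compute the moments on the residual graph (the alternative — original
moments scaled by (1−α) — is not what the percolation argument needs).

The Monte-Carlo threshold estimator sweeps a p-grid, averages the
largest-component fraction over seeded replicates, and reports the first
grid point crossing an emergence cutoff of 0.05 of the nodes (the
asymptotic theory gives only the location of the transition; the cutoff is
configurable, and at n = 2000 it places the crossing within ~5% of the
theoretical point). A grid entirely above threshold yields a warning and
the first grid point; a grid entirely below raises.

**Mean field.** Homogeneous networks follow the logistic equation
`di/dt = λ⟨k⟩ i(1−i)` (closed form returned directly). Heterogeneous
networks track per-degree densities `di_k/dt = λ k θ(t) (1 − i_k)` with
the uncorrelated-network neighbor field θ(t) = Σ_k k P(k) i_k / ⟨k⟩,
integrated numerically, alongside the early-time exponential closed form
`i_k(t) = i0 [1 + k⟨k⟩/(⟨k²⟩−⟨k⟩)(e^{t/τ} − 1)]`, capped at 1.

*Time-constant caveat.* Two versions of τ circulate. The form this package
exposes as `tau`, ⟨k²⟩/(λ(⟨k²⟩−⟨k⟩)), follows the printed description of
the model; the form that makes the closed form consistent with the density
equations themselves — and the one in the mean-field literature the model
descends from — has ⟨k⟩ in the numerator and is exposed as
`tau_consistent`. They differ by the factor ⟨k²⟩/⟨k⟩, which is large
exactly when the network is strongly heterogeneous. With `tau` the closed
form does not track the integrated equations even at early times; with
`tau_consistent` it does (within a few percent for t ≲ 0.25τ at the
moments used in the tests). `meanfield_degree_based` defaults to `tau` for
fidelity and accepts either; the unit suite demonstrates the consistent
variant, and the acceptance suite records the discrepancy of the default.

**Agent-based contagion.** Synchronous discrete-time updates (no scheduler
is prescribed by the conceptual model; synchronous updates are
reproducible and match the mean-field comparisons): each adopter with
positive `behavioral_degree` (diffusion strength in [0, 1], default 1 for
every agent; heterogeneous per-node values accepted) transmits to each
susceptible non-immune neighbor independently with probability
transmit_prob × behavioral_degree; susceptibles also adopt spontaneously
with a per-step probability. There is no recovery in this process, so
adoption counts are non-decreasing. Transmission is implemented by summing
per-adopter log miss-probabilities through the sparse adjacency matrix,
which keeps 5000-node, 200-replicate experiments in seconds. When
comparing simulated final sizes with the analytic r, runs are conditioned
on an outbreak (> 1% adopted), since r describes the giant-outbreak branch
only. The correspondence between this no-recovery agent process and the
SIS-style mean-field equations is early-time only; we document rather than
resolve this.

## Dyadic information measures

The contagion of an event of probability p is its surprisal
I(p) = log(1/p); entropies use the 0·log(1/0) := 0 convention. All
computation is in natural log internally with conversion at the interface
(bases 2/3/e/10 → bits/trits/nats/Hartleys; default bits). Kraft–McMillan
feasibility and the source-coding bound S ≤ L·log β are computed directly.
Mutual contagion and all conditional/joint entropies come from direct
summation over the joint matrix; the chain-rule identities hold to 1e-9 by
construction. Channel capacity uses Blahut–Arimoto alternating
maximization with the standard capacity bracket (Σp·D ≤ C ≤ max D) as the
stopping rule; the iteration is monotone and the bracket makes the
reported value reliable to the requested tolerance. The dyadic channel is
conventionally characterized backward, by {P(f_i | g_j)};
`reverse_channel_to_forward` converts to the forward orientation over
which capacity is defined, and both orientations are public. Degenerate
(deterministic) rows are handled by the zero-mass convention.

Maximum-entropy distributions under linear constraints Σ f_i s_i^(r) = s_r
are solved in the dual: minimizing ln H(λ) + λ·s (H the partition sum) by
BFGS with analytic gradient, which is convex and smooth; the primal is
recovered as the exponential family f_i ∝ exp(−Σ λ_r s_i^(r)), and the
normalization multiplier ln H is reported. Targets outside the convex hull
of the constraint values, or on its boundary (where multipliers diverge),
raise `InfeasibleConstraints`.

## Physiological indexes

Time-domain HRV: AVNN (mean NN interval), SDNN (sample standard deviation,
ddof = 1), RMSSD (root mean square of successive differences), pNN50
(percentage of successive differences with magnitude strictly above
50 ms). Frequency-domain HRV: the NN series is resampled at 4 Hz by linear
interpolation at cumulative beat times, mean-removed, and band powers
integrated from the periodogram — VLF < 0.04 Hz, LF 0.04–0.15 Hz, HF from
0.15 Hz to an upper bound of 0.4 Hz by default (0.5 Hz is also in use;
the bound is a parameter). TOTPWR is the total power below the HF upper
bound, and normalized units are LFnu = 100·LF/(σ²_RR − VLF), analogously
HFnu, with σ²_RR the tachogram variance. At least 60 s of data is
required. EMG envelopes are non-overlapping-window RMS; respiration depth
is the per-cycle max-minus-min between detected inspiration peaks
(prominence 0.25 of the signal span), period the mean peak spacing, rate
60/period, with a flat/peakless trace yielding depth 0 and NaN rate
rather than an exception so depth stays accessible. EEG frontal asymmetry
is (right − left)/(right + left) alpha power. RSA has no single standard
computation (peak-valley vs spectral) and is accepted as a precomputed
index only.

## Calibration rule

Deltas are signed baseline-relative changes Δ = (value − baseline)/|baseline|
for physiological indexes — making the stress threshold ST, a percentage,
comparable across indexes with different units — and raw post-minus-pre
differences for the self-report scales (SUS presence, PMQ anxiety/relax).
Zero baselines flag the delta missing; missing deltas never trigger the
rule.

Each index has a stress direction (+1 rises under stress, −1 falls:
corrugator EMG, skin conductance, LF, LF/HF, total power, beta power and
anxiety rise; zygomatic EMG, respiration amplitude/period, RSA, HF, pNN50,
RMSSD, SDNN, AVNN, alpha power, right-alpha asymmetry and relaxation
fall). The direction table is configurable. A sub-rule triggers when
direction × Δ > ST; writing the decrease-type comparisons as Δ < −ST
resolves the printed rule's "Δ < ST" comparisons, which would otherwise be
satisfied almost always. A (subject, condition) is flagged stressed when
any of these clause blocks fires:

1. facial/electrodermal: (zygomatic fall OR corrugator rise) AND skin
   conductance rise — the brace nesting is read with electrodermal arousal
   as the conjunctive gate;
2. autonomic: any single cardiorespiratory/HRV sub-rule;
3. combination: at least `ntuple_min` (default 2, "a couple"; the tuple
   size is not fixed by the source rule) of the autonomic + EEG sub-rules
   simultaneously — EEG indexes participate only here, matching their
   placement in the rule;
4. presence: ΔSUS > 0, as printed, switchable via `include_sus`
   (default on);
5. self-report: anxiety rise beyond ST or relaxation fall beyond ST.

Per group, AdoptionFraction is the proportion of subjects flagged in the
cognitive stress task, and ImitationEffectiveness the mean flagged
proportion across the four media conditions (VR/audio/text/video). The
source states only that flags move the parameters upward; the
proportion-of-flagged-subjects estimator is this package's documented
choice, and it maps naturally onto the probability semantics of both
parameters. Raising ST can only unflag, so threshold-sweep curves are
non-increasing — except through the presence clause, which ignores ST;
monotonicity is therefore verified with `include_sus=False` and documented
with it on.

## Synthetic cohort

The generator emulates the *index-table level* of a two-group,
six-condition study: 26 + 16 subjects by default, baselines drawn
uniformly from plausible resting ranges (documented as code constants;
e.g. AVNN 700–1000 ms, SDNN 30–80 ms, skin conductance 2–10 µS), and in
each stimulus condition a subject responds with the group's responder
probability (defaults 0.8/0.4). Responders shift every index by a relative
effect size (default 0.25 of baseline) in its stress direction — the
directions follow the calibration table, so ground truth and rule agree by
construction — and all values carry multiplicative Gaussian noise
(default sd 0.05 of baseline, i.e. effects are five times the noise).
NN-interval series are synthesized with modulation tones at the LF/HF band
centers (0.10/0.30 Hz) for clean spectral separation, floored at 200 ms.

What passing recovery tests show: under index-level responder/noise
structure, the rule-plus-estimator pipeline recovers responder
probabilities within binomial sampling error. What they do not show:
robustness to waveform-level artifacts, within-subject correlation across
indexes, non-stationary baselines, or real effect-size heterogeneity —
none of which the generator models.

Recovery experiments are run with `include_sus=False`: the presence clause
thresholds at zero, so for a non-responder it fires on the sign of noise
alone (≈50% false-positive rate) and no responder share below ~0.5 would
be recoverable with it active. This is a property of the rule as printed,
not of the cohort; with the clause off, the remaining false-positive
channel (raw self-report deltas against ST) contributes only a few
percent.

## Policy layer

The integrated model is an explicitly simplified reconstruction: the
source names the coupling between agent outputs, a threshold and a
discrete-event policy block but gives no equations. Here each agent's
internal output is its adoption state smoothed exponentially (smoothing
constant configurable, default 1 = raw state); agents above the output
threshold enqueue one behavior-change request (no duplicates while
queued); a FIFO server processes up to `service_capacity` requests per
step, each reverting the agent to susceptible with `success_prob`. FIFO
with one outstanding request per agent is the simplest discipline
consistent with a single service block.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed (numpy `default_rng` /
`SeedSequence` streams; same seed → bit-identical graphs, trajectories and
cohorts). The scenario runner writes a manifest (config echo, seed,
versions) sufficient to re-run a scenario exactly.

Problem sizes in the test and acceptance experiments — n = 2000 with 30
replicates per grid point for the percolation sweep, n = 5000 with 200
replicates for the outbreak comparison, 100 cohort replicates for
calibration recovery — were chosen so Monte-Carlo error sits comfortably
inside the assertion tolerances (e.g. ±0.2 on a threshold location of 1,
±0.05 on an outbreak fraction of 0.797) while individual experiments
complete in seconds to a few minutes.

## Known limitations

- The closed-form adoption solution covers S(0) = 0 only.
- The degree-based mean field exposes the printed time constant by
  default; see the caveat above.
- The agent simulator has no recovery, so it matches SIS-style mean-field
  equations only at early times.
- The calibration estimator assumes one flag per subject-condition; it
  does not model within-subject dependence across conditions.
- The policy layer is a reconstruction, not a reproduction, of the
  integrated model.
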
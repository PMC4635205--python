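# behaviordyn

Simulators and calibration tools for **behavior contagion** — the spread
of a behavior (stress, a habit, an adoption decision) through a
population — together with the psychophysiological measurement layer that
turns lab recordings into the simulators' input parameters.

The package is aimed at computational psychometrics / behavioral
epidemiology work: you measure how readily individuals contract a behavior
directly and by imitation, and then ask how that behavior diffuses through
a population or a contact network.

## What's inside

| module | contents |
| --- | --- |
| `behaviordyn.diffusion` | difference-equation adoption model `S(t)=S(t−1)+α(1−S(t−1))+β(1−S(t−1))S(t−1)`, its continuous closed form, a stock-and-flow word-of-mouth adoption model (AdoptionFromImitation / AdoptionFromWOM), SIR, time-to-adoption utilities |
| `behaviordyn.networks` | Poisson / preferential-attachment / configuration-model graphs, immune-node removal, giant-component and percolation-threshold analytics (`p(1−α)n = 1`, `r = 1−e^{−r(1−α)np}`, `⟨d²⟩ = 2⟨d⟩`), homogeneous and degree-based mean-field spreading, synchronous agent-based contagion with per-agent `behavioral_degree` |
| `behaviordyn.information` | dyadic contagion measures: surprisal I(p)=log(1/p), entropy, Kraft–McMillan / source-coding bounds, mutual contagion I(F;G), channel capacity (Blahut–Arimoto), maximum-entropy distributions under macroscopic constraints |
| `behaviordyn.physio` | HRV time/frequency-domain indexes, EMG RMS envelopes, respiration features, EEG alpha asymmetry; baseline deltas, the stress-threshold (ST) flagging rule, and per-group estimation of **AdoptionFraction** and **ImitationEffectiveness** |
| `behaviordyn.cohort` | synthetic cohorts (two groups, six conditions, twenty indexes) with known responder shares, for end-to-end parameter-recovery testing; mapping of calibration results into runnable scenarios |
| `behaviordyn.policy` | integrated model: network contagion + capacity-limited FIFO policy layer that reverts adopters on request |
| `behaviordyn.run` / CLI | config-driven scenario runner with manifests; `behaviordyn simulate|calibrate|synth|sweep|analyze-network` |

The core calibration idea: a cohort is exposed to a direct stressor (a
cognitive task) and to four media renditions of *other people's* stress
(VR, audio, text, video). A subject whose physiological deltas cross the
stress threshold ST is flagged; the flagged proportion in the task
condition estimates AdoptionFraction, and the mean flagged proportion
across the media conditions estimates ImitationEffectiveness. Both feed
the stock-and-flow diffusion model directly.

## Worked example

```bash
python examples/calibration_pipeline.py
```

```
cohort: 42 subjects, 20 indexes, 6 conditions
 group  n_subjects  adoption_fraction  imitation_effectiveness
female          26           0.769231                 0.788462
  male          16           0.500000                 0.468750
ground truth:
 group  adoption_fraction  imitation_effectiveness
female                0.8                      0.8
  male                0.4                      0.4
...
group female: 90% of the population adopts by t = 0.10
group male: 90% of the population adopts by t = 0.14
```

A synthetic cohort shaped like the reference study design (26 female + 16
male subjects) is generated with responder probabilities 0.8 / 0.4; the
stress rule at ST = 0.2 recovers those shares to within binomial sampling
error (0.77 / 0.50 here), and the calibrated two-group diffusion scenario
shows the higher-propensity group adopting the behavior faster — the
group with both parameters larger reaches 90% population adoption in
roughly 70% of the time.

Other examples, one per capability (each prints its numbers and what they
mean):

```bash
python examples/diffusion_models.py     # recurrence / closed form / SD / SIR
python examples/network_contagion.py    # percolation threshold, outbreak size, mean field
python examples/dyadic_information.py   # entropy, capacity, max-ent
python examples/policy_intervention.py  # contagion under a policy layer
```

For instance `network_contagion.py` prints

```
giant component emerges at p(1-alpha)n = 0.95 (theory: 1)
coupling c = 2.0: expected outbreak fraction r = 0.7968
agent-based mean outbreak (conditioned) = 0.7966 vs analytic 0.7968
```

— the Monte-Carlo emergence point of the giant component sits at the
theoretical unit coupling, and the agent-based simulator reproduces the
analytic outbreak fraction `r = 1 − e^{−cr}` to three decimals.

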
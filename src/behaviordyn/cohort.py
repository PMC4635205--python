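"""Synthetic cohorts with known ground truth for end-to-end testing.

Real psychophysiological recordings for this design (two groups, six
conditions, twenty indexes) are not deposited anywhere, so the package
ships a generator that emulates the *index-level* structure of such a
study: per-subject baselines drawn from plausible physiological ranges, a
known share of "stress responders" per condition whose indexes shift in
the stress direction by a configurable effect size, and index-specific
relative noise. Waveform-level realism (ECG/EEG morphology) is explicitly
out of scope; what the generator supports is parameter-recovery testing of
the calibration rule and seeding of the downstream diffusion scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .diffusion import SDAdoptionParams
from .physio import (
    BASELINE,
    CONDITIONS,
    MEDIA_CONDITIONS,
    PHYSIO_INDEXES,
    SELF_REPORT_INDEXES,
    STRESS_DIRECTIONS,
    TASK_CONDITION,
    CalibrationResult,
)

__all__ = [
    "BASELINE_RANGES",
    "CohortSpec",
    "GroundTruth",
    "generate_nn_series",
    "generate_index_table",
    "scenario_from_calibration",
]

#: Plausible baseline magnitude ranges per index (uniform draw bounds).
#: Values are ordinary resting magnitudes for healthy young adults; the
#: lower bounds are strictly positive so baseline-relative deltas are
#: always defined.
BASELINE_RANGES: dict[str, tuple[float, float]] = {
    "EMG-Z": (2.0, 8.0),        # uV RMS
    "EMG-CS": (2.0, 8.0),       # uV RMS
    "SC_Mean": (2.0, 10.0),     # uS
    "RSP_Amp": (0.3, 0.8),      # arbitrary strain-gauge units
    "RSP_Period": (3.0, 5.0),   # s
    "RSA": (20.0, 60.0),        # ms peak-valley
    "LFbyHF": (0.8, 2.5),
    "HF": (300.0, 1200.0),      # ms^2
    "LF": (400.0, 1500.0),      # ms^2
    "TOTPWR": (1500.0, 4000.0), # ms^2
    "pNN50": (5.0, 40.0),       # %
    "rMSSD": (20.0, 60.0),      # ms
    "SDNN": (30.0, 80.0),       # ms
    "AVNN": (700.0, 1000.0),    # ms
    "Alpha": (10.0, 40.0),      # uV^2
    "Beta": (5.0, 25.0),        # uV^2
    "EEG_Asym": (0.05, 0.30),
    "SUS": (2.0, 5.0),          # presence score, 1-7
    "PMQ_Anxiety": (1.0, 3.0),  # anxiety scale
    "PMQ_Relax": (2.0, 4.0),    # relaxation scale
}

_STIMULUS_CONDITIONS = (*MEDIA_CONDITIONS, TASK_CONDITION)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the reference study design: 26 + 16 subjects in two
    gender groups, responder probability 0.8 (female) / 0.4 (male) in every
    stimulus condition, effect size 0.25 of baseline (five times the 0.05
    relative noise) in each index's stress direction.
    """

    n_subjects: Mapping[str, int] = field(
        default_factory=lambda: {"female": 26, "male": 16}
    )
    responder_prob: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.8, "male": 0.4}
    )
    effect_size: Mapping[str, float] | float = 0.25
    noise_sd: Mapping[str, float] | float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for g, n in self.n_subjects.items():
            if n < 1:
                raise ValueError(f"group {g!r} must have at least one subject")
        for g in self.n_subjects:
            p = self._responder_prob(g, TASK_CONDITION)
            if not 0.0 <= p <= 1.0:
                raise ValueError("responder probabilities must be in [0, 1]")
        if np.any(np.asarray(list(self._per_index(self.noise_sd).values())) < 0):
            raise ValueError("noise_sd must be non-negative")

    @staticmethod
    def _per_index(value) -> dict[str, float]:
        if isinstance(value, Mapping):
            out = {idx: float(value.get(idx, 0.0)) for idx in BASELINE_RANGES}
            return out
        return {idx: float(value) for idx in BASELINE_RANGES}

    def _responder_prob(self, group: str, condition: str) -> float:
        p = self.responder_prob[group]
        if isinstance(p, Mapping):
            return float(p[condition])
        return float(p)


@dataclass(frozen=True)
class GroundTruth:
    """Responder indicators and the calibration values they imply."""

    responders: pd.DataFrame  # subject, group, condition, responder
    expected: pd.DataFrame    # group, adoption_fraction, imitation_effectiveness

    def realized(self) -> pd.DataFrame:
        """Realized (sampled) responder shares per group, in the same shape
        as the expected table."""
        rows = []
        for group, sub in self.responders.groupby("group", sort=True):
            task = sub[sub["condition"] == TASK_CONDITION]["responder"]
            media = [
                sub[sub["condition"] == c]["responder"].mean() for c in MEDIA_CONDITIONS
            ]
            rows.append(
                {
                    "group": group,
                    "adoption_fraction": float(task.mean()),
                    "imitation_effectiveness": float(np.mean(media)),
                }
            )
        return pd.DataFrame(rows)


def generate_nn_series(
    duration_s: float = 300.0,
    mean_ibi_ms: float = 800.0,
    lf_amp_ms: float = 30.0,
    hf_amp_ms: float = 20.0,
    noise_sd_ms: float = 10.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Synthetic NN-interval series with LF and HF modulation.

    NN_i = mean + lf_amp sin(2 pi 0.10 t_i) + hf_amp sin(2 pi 0.30 t_i) +
    Gaussian noise, floored at 200 ms. The modulation frequencies sit at
    the band centers (0.10 / 0.30 Hz) so spectral indexes separate cleanly.
    Raises if the requested parameters would produce non-positive raw
    intervals at more than a 1% rate.
    """
    if duration_s <= 0 or mean_ibi_ms <= 0:
        raise ValueError("duration_s and mean_ibi_ms must be positive")
    if min(lf_amp_ms, hf_amp_ms, noise_sd_ms) < 0:
        raise ValueError("amplitudes and noise must be non-negative")
    rng = np.random.default_rng(seed)
    intervals = []
    n_nonpos = 0
    t = 0.0
    while t < duration_s:
        raw = (
            mean_ibi_ms
            + lf_amp_ms * np.sin(2 * np.pi * 0.10 * t)
            + hf_amp_ms * np.sin(2 * np.pi * 0.30 * t)
            + (rng.normal(0.0, noise_sd_ms) if noise_sd_ms > 0 else 0.0)
        )
        if raw <= 0:
            n_nonpos += 1
        nn = max(raw, 200.0)
        intervals.append(nn)
        t += nn / 1000.0
    series = np.asarray(intervals)
    if n_nonpos > 0.01 * series.size:
        raise ValueError(
            "parameters produce non-positive raw intervals at >1% rate; "
            "reduce amplitudes or noise"
        )
    return series


def generate_index_table(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Synthetic per-subject index table plus its ground truth.

    Baselines are drawn per subject and index from :data:`BASELINE_RANGES`.
    In each stimulus condition a subject is a responder with the group's
    responder probability (independent across conditions); responders
    receive a shift of ``effect_size`` times baseline in the index's stress
    direction, and every value carries multiplicative Gaussian noise of sd
    ``noise_sd`` times baseline. Self-report scales follow the same scheme
    on their own scales (their deltas are raw differences downstream).
    """
    rng = np.random.default_rng(spec.seed)
    effect = CohortSpec._per_index(spec.effect_size)
    noise = CohortSpec._per_index(spec.noise_sd)
    indexes = list(BASELINE_RANGES)
    records = []
    truth_rows = []
    subject_id = 0
    for group in sorted(spec.n_subjects):
        for _ in range(spec.n_subjects[group]):
            subject = f"S{subject_id:03d}"
            subject_id += 1
            baselines = {
                idx: rng.uniform(*BASELINE_RANGES[idx]) for idx in indexes
            }
            for idx in indexes:
                records.append(
                    (subject, group, BASELINE, idx, baselines[idx])
                )
            for cond in _STIMULUS_CONDITIONS:
                responder = rng.random() < spec._responder_prob(group, cond)
                truth_rows.append((subject, group, cond, responder))
                for idx in indexes:
                    shift = (
                        STRESS_DIRECTIONS[idx] * effect[idx] if responder else 0.0
                    )
                    eps = rng.normal(0.0, noise[idx]) if noise[idx] > 0 else 0.0
                    value = baselines[idx] * (1.0 + shift + eps)
                    records.append((subject, group, cond, idx, value))
    table = pd.DataFrame(
        records, columns=["subject", "group", "condition", "index", "value"]
    )
    responders = pd.DataFrame(
        truth_rows, columns=["subject", "group", "condition", "responder"]
    )
    expected = pd.DataFrame(
        [
            {
                "group": g,
                "adoption_fraction": spec._responder_prob(g, TASK_CONDITION),
                "imitation_effectiveness": float(
                    np.mean([spec._responder_prob(g, c) for c in MEDIA_CONDITIONS])
                ),
            }
            for g in sorted(spec.n_subjects)
        ]
    )
    return table, GroundTruth(responders=responders, expected=expected)


def scenario_from_calibration(
    result: CalibrationResult, total_population: float, contact_rate: float
) -> dict[str, SDAdoptionParams]:
    """Map calibrated parameters into ready-to-run diffusion scenarios.

    The estimated AdoptionFraction and ImitationEffectiveness become the
    corresponding fixed factors of the stock-and-flow adoption model, one
    parameter set per group, with shared population size and contact rate.
    """
    scenarios = {}
    for _, row in result.per_group.iterrows():
        scenarios[str(row["group"])] = SDAdoptionParams(
            total_population=total_population,
            contact_rate=contact_rate,
            adoption_fraction=float(row["adoption_fraction"]),
            imitation_effectiveness=float(row["imitation_effectiveness"]),
        )
    return scenarios
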
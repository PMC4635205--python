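"""Psychophysiological indexes and stress-threshold calibration.

A cohort of subjects is measured at Baseline and under five stimulus
conditions (VR, AUDIO, TEXT, VIDEO and a COGNITIVE_TASK). Per subject and
condition a table of stress-sensitive indexes is formed: facial EMG
(zygomatic and corrugator RMS), skin conductance, respiration amplitude and
period, heart-rate-variability time- and frequency-domain indexes, EEG band
powers and frontal alpha asymmetry, and self-report scales (presence and
post-media anxiety/relaxation).

Calibration turns these tables into the two diffusion-model inputs:

* ``AdoptionFraction``  — proportion of subjects whose indexes cross a
  stress threshold (ST) during the cognitive stress task (direct propensity
  to contract the behavior);
* ``ImitationEffectiveness`` — mean flagged proportion over the four media
  conditions, in which stress is elicited by exposure to *other people's*
  stress (propensity to imitate).

A subject/condition is flagged stressed when its baseline-relative index
changes satisfy an OR of clause blocks (facial+electrodermal conjunction,
any single autonomic shift, an n-tuple of simultaneous autonomic/EEG
shifts, or self-report shifts); all thresholds compare the *signed relative
change* against ST in each index's stress direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, periodogram

__all__ = [
    "CONDITIONS",
    "BASELINE",
    "MEDIA_CONDITIONS",
    "TASK_CONDITION",
    "PHYSIO_INDEXES",
    "SELF_REPORT_INDEXES",
    "STRESS_DIRECTIONS",
    "HRVTimeDomain",
    "SpectralPowers",
    "RespirationFeatures",
    "StressRuleConfig",
    "CalibrationResult",
    "hrv_time_domain",
    "hrv_frequency_domain",
    "emg_rms",
    "respiration_features",
    "eeg_asymmetry",
    "compute_deltas",
    "apply_stress_rule",
    "estimate_parameters",
    "threshold_sweep",
]

BASELINE = "Baseline"
MEDIA_CONDITIONS = ("VR", "AUDIO", "TEXT", "VIDEO")
TASK_CONDITION = "COGNITIVE_TASK"
CONDITIONS = (BASELINE, *MEDIA_CONDITIONS, TASK_CONDITION)

#: Stress direction per index: +1 if the index rises under stress, -1 if it
#: falls. An index triggers its sub-rule when direction * delta > ST.
STRESS_DIRECTIONS: dict[str, int] = {
    "EMG-Z": -1,      # zygomatic (positive affect) activity drops
    "EMG-CS": +1,     # corrugator (negative affect) activity rises
    "SC_Mean": +1,    # electrodermal arousal rises
    "RSP_Amp": -1,    # shallower breathing
    "RSP_Period": -1, # faster breathing
    "RSA": -1,        # vagal tone drops
    "LFbyHF": +1,     # sympathovagal balance shifts sympathetic
    "HF": -1,
    "LF": +1,
    "TOTPWR": +1,
    "pNN50": -1,
    "rMSSD": -1,
    "SDNN": -1,
    "AVNN": -1,       # shorter beats = higher heart rate
    "Alpha": -1,      # cortical activation suppresses alpha
    "Beta": +1,
    "EEG_Asym": -1,   # right-alpha prevalence drops with right activation
    "SUS": +1,
    "PMQ_Anxiety": +1,
    "PMQ_Relax": -1,
}

#: Indexes whose deltas are baseline-relative changes.
PHYSIO_INDEXES = (
    "EMG-Z", "EMG-CS", "SC_Mean", "RSP_Amp", "RSP_Period", "RSA", "LFbyHF",
    "HF", "LF", "TOTPWR", "pNN50", "rMSSD", "SDNN", "AVNN", "Alpha", "Beta",
    "EEG_Asym",
)
#: Indexes whose deltas are raw post-minus-pre differences on their own scale.
SELF_REPORT_INDEXES = ("SUS", "PMQ_Anxiety", "PMQ_Relax")

_AUTONOMIC = ("RSA", "LFbyHF", "HF", "LF", "TOTPWR", "pNN50", "rMSSD", "SDNN", "AVNN")
_EEG = ("Alpha", "Beta", "EEG_Asym")


# ---------------------------------------------------------------------------
# Index computation from raw-ish series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRVTimeDomain:
    avnn: float   # mean NN interval, ms
    sdnn: float   # sample standard deviation of NN intervals, ms
    rmssd: float  # root mean square of successive differences, ms
    pnn50: float  # % of successive differences with magnitude > 50 ms


def hrv_time_domain(nn_ms: Sequence[float]) -> HRVTimeDomain:
    """Time-domain heart-rate-variability indexes from NN intervals (ms)."""
    nn = np.asarray(nn_ms, dtype=float)
    if nn.ndim != 1 or nn.size < 2:
        raise ValueError("need at least two NN intervals")
    if np.any(nn <= 0):
        raise ValueError("NN intervals must be positive")
    diffs = np.diff(nn)
    return HRVTimeDomain(
        avnn=float(nn.mean()),
        sdnn=float(nn.std(ddof=1)),
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        pnn50=float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / diffs.size),
    )


@dataclass(frozen=True)
class SpectralPowers:
    """Absolute band powers of the NN tachogram (ms^2) plus normalized units.

    lf_nu = 100 * LF / (sigma^2_RR - VLF) and analogously hf_nu, where
    sigma^2_RR is the variance of the tachogram.
    """

    vlf: float
    lf: float
    hf: float
    totpwr: float
    lf_nu: float
    hf_nu: float
    lf_hf: float
    rr_variance: float


def hrv_frequency_domain(
    nn_ms: Sequence[float],
    resample_hz: float = 4.0,
    vlf_upper_hz: float = 0.04,
    lf_upper_hz: float = 0.15,
    hf_upper_hz: float = 0.4,
) -> SpectralPowers:
    """Frequency-domain HRV indexes from NN intervals.

    The NN series is placed at cumulative beat times, evenly resampled at
    ``resample_hz`` by linear interpolation, mean-removed, and band powers
    are integrated from the periodogram: VLF below 0.04 Hz, LF 0.04-0.15 Hz,
    HF 0.15 Hz up to ``hf_upper_hz`` (0.4 Hz by default; 0.5 Hz is also in
    use and can be selected). TOTPWR is the total power below the HF upper
    bound. Requires at least 60 s of data.
    """
    nn = np.asarray(nn_ms, dtype=float)
    if nn.ndim != 1 or nn.size < 2 or np.any(nn <= 0):
        raise ValueError("need a series of positive NN intervals")
    t = np.cumsum(nn) / 1000.0  # beat times, s
    duration = t[-1] - t[0]
    if duration < 60.0:
        raise ValueError("recording too short: need >= 60 s of intervals")
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tachogram = np.interp(grid, t, nn)
    rr_var = float(tachogram.var())
    freqs, psd = periodogram(tachogram, fs=resample_hz, detrend="constant")
    df = freqs[1] - freqs[0]

    def band(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs < hi)
        return float(psd[sel].sum() * df)

    vlf = band(0.0, vlf_upper_hz)
    lf = band(vlf_upper_hz, lf_upper_hz)
    hf = band(lf_upper_hz, hf_upper_hz)
    totpwr = band(0.0, hf_upper_hz)
    denom = rr_var - vlf
    lf_nu = 100.0 * lf / denom if denom > 0 else math.nan
    hf_nu = 100.0 * hf / denom if denom > 0 else math.nan
    return SpectralPowers(
        vlf=vlf, lf=lf, hf=hf, totpwr=totpwr,
        lf_nu=lf_nu, hf_nu=hf_nu,
        lf_hf=lf / hf if hf > 0 else math.inf,
        rr_variance=rr_var,
    )


def emg_rms(signal: Sequence[float], window: int) -> np.ndarray:
    """Windowed RMS envelope of a raw EMG trace.

    The raw signal is rectified by the root mean square over consecutive
    non-overlapping windows of ``window`` samples; a trailing partial window
    is dropped.
    """
    x = np.asarray(signal, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.size:
        raise ValueError("window longer than signal")
    n_win = x.size // window
    chunks = x[: n_win * window].reshape(n_win, window)
    return np.sqrt(np.mean(chunks**2, axis=1))


@dataclass(frozen=True)
class RespirationFeatures:
    depth: float    # mean per-cycle max minus min, signal units
    period: float   # mean peak-to-peak spacing, s (NaN if undefined)
    rate: float     # breaths per minute (NaN if undefined)


def respiration_features(signal: Sequence[float], fs: float) -> RespirationFeatures:
    """Breathing depth, period and rate from a respiration trace.

    Depth is the point of maximum inspiration minus the point of maximum
    expiration within each breath cycle, averaged over cycles; the period
    comes from peak-to-peak spacing and the rate is 60/period. A trace with
    no detectable breath peaks yields depth 0 and NaN period/rate (the
    undefined-rate signal).
    """
    x = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if x.size < 3:
        raise ValueError("signal too short")
    span = x.max() - x.min()
    if span == 0:
        return RespirationFeatures(depth=0.0, period=math.nan, rate=math.nan)
    peaks, _ = find_peaks(x, prominence=0.25 * span)
    if peaks.size < 2:
        return RespirationFeatures(depth=0.0, period=math.nan, rate=math.nan)
    depths = [float(x[a:b].max() - x[a:b].min()) for a, b in zip(peaks[:-1], peaks[1:])]
    period = float(np.mean(np.diff(peaks)) / fs)
    return RespirationFeatures(depth=float(np.mean(depths)), period=period, rate=60.0 / period)


def eeg_asymmetry(alpha_right: float, alpha_left: float) -> float:
    """Frontal alpha-asymmetry index (right - left) / (right + left).

    Positive values indicate prevalence of alpha in the right hemisphere
    (relatively more left activation); the index falls under stress as
    right-hemisphere activation suppresses right alpha.
    """
    if alpha_right < 0 or alpha_left < 0:
        raise ValueError("band powers must be non-negative")
    total = alpha_right + alpha_left
    if total == 0:
        raise ValueError("both hemispheric powers are zero")
    return (alpha_right - alpha_left) / total


# ---------------------------------------------------------------------------
# Delta table and the stress-threshold rule
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["subject", "group", "condition", "index", "value"]


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"index table missing columns: {missing}")
    dup = table.duplicated(subset=["subject", "condition", "index"])
    if dup.any():
        raise ValueError("one value per (subject, condition, index) required")
    return table


def compute_deltas(table: pd.DataFrame) -> pd.DataFrame:
    """Baseline-relative changes per (subject, non-baseline condition, index).

    Physiological indexes: delta = (value - baseline) / |baseline|, so the
    stress threshold (a percentage) is comparable across indexes with
    different units. Self-report scales (SUS, PMQ) use the raw difference.
    A zero physiological baseline yields a missing delta (flagged, never a
    rule trigger). Every physiological index present in a non-baseline
    condition must have a Baseline row for that subject.
    """
    table = _validate_table(table)
    base = (
        table[table["condition"] == BASELINE]
        .set_index(["subject", "index"])["value"]
    )
    cond = table[table["condition"] != BASELINE].copy()
    key = pd.MultiIndex.from_frame(cond[["subject", "index"]])
    has_base = np.asarray(key.isin(base.index))
    physio_mask = cond["index"].isin(PHYSIO_INDEXES).to_numpy()
    if np.any(physio_mask & ~has_base):
        bad = cond.loc[physio_mask & ~has_base, ["subject", "index"]]
        raise ValueError(f"missing Baseline rows for: {bad.drop_duplicates().values.tolist()}")
    baseline_vals = pd.Series(
        np.where(has_base, base.reindex(key).to_numpy(), np.nan), index=cond.index
    )
    raw_diff = cond["value"].to_numpy() - baseline_vals.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = raw_diff / np.abs(baseline_vals.to_numpy())
    delta = np.where(physio_mask, rel, raw_diff)
    missing = ~np.isfinite(delta)
    out = cond[["subject", "group", "condition", "index"]].copy()
    out["delta"] = np.where(missing, np.nan, delta)
    out["missing"] = missing
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class StressRuleConfig:
    """Configuration of the stress-threshold flagging rule.

    st          : stress threshold ST in [0, 1], a relative-change magnitude
    ntuple_min  : minimum number of simultaneous autonomic/EEG sub-rules in
                  the combination block (a couple by default)
    include_sus : keep the presence clause (delta SUS > 0) as printed; it
                  ignores ST and fires on any increase, so it can be
                  disabled for threshold-semantics analyses
    directions  : stress direction per index (+1 rise / -1 fall)
    """

    st: float = 0.2
    ntuple_min: int = 2
    include_sus: bool = True
    directions: Mapping[str, int] = field(default_factory=lambda: dict(STRESS_DIRECTIONS))

    def __post_init__(self) -> None:
        if not 0.0 <= self.st <= 1.0:
            raise ValueError("st must be in [0, 1]")
        if self.ntuple_min < 2:
            raise ValueError("ntuple_min must be >= 2")


def apply_stress_rule(deltas: pd.DataFrame, cfg: StressRuleConfig) -> pd.DataFrame:
    """Flag each (subject, condition) as stressed or not, with a rule trace.

    A record is flagged when any clause fires:

    * ``facial_electrodermal`` — (EMG-Z falls OR EMG-CS rises beyond ST)
      AND skin conductance rises beyond ST;
    * ``autonomic`` — any single autonomic index shifts beyond ST in its
      stress direction;
    * ``combination`` — at least ``ntuple_min`` of the autonomic + EEG
      sub-rules hold simultaneously;
    * ``sus`` — presence score increased (any amount), if ``include_sus``;
    * ``self_report`` — anxiety rose beyond ST or relaxation fell beyond ST.

    Missing deltas never trigger. Returns one row per (subject, group,
    condition) with columns ``flagged`` and ``clauses`` (comma-joined names
    of the clauses that fired).
    """
    pivot = (
        deltas.set_index(["subject", "group", "condition", "index"])["delta"]
        .unstack("index")
    )

    def trig(idx: str) -> pd.Series:
        if idx not in pivot.columns:
            return pd.Series(False, index=pivot.index)
        d = pivot[idx]
        direction = cfg.directions.get(idx, +1)
        return (direction * d > cfg.st).fillna(False)

    facial = (trig("EMG-Z") | trig("EMG-CS")) & trig("SC_Mean")
    autonomic = pd.Series(False, index=pivot.index)
    combo_count = pd.Series(0, index=pivot.index)
    for idx in _AUTONOMIC:
        t = trig(idx)
        autonomic |= t
        combo_count += t.astype(int)
    for idx in _EEG:
        combo_count += trig(idx).astype(int)
    combination = combo_count >= cfg.ntuple_min
    if cfg.include_sus and "SUS" in pivot.columns:
        sus = (pivot["SUS"] > 0).fillna(False)
    else:
        sus = pd.Series(False, index=pivot.index)
    anx = (pivot["PMQ_Anxiety"] > cfg.st).fillna(False) if "PMQ_Anxiety" in pivot.columns \
        else pd.Series(False, index=pivot.index)
    relax = (pivot["PMQ_Relax"] < -cfg.st).fillna(False) if "PMQ_Relax" in pivot.columns \
        else pd.Series(False, index=pivot.index)
    self_report = anx | relax

    clauses = pd.DataFrame(
        {
            "facial_electrodermal": facial,
            "autonomic": autonomic,
            "combination": combination,
            "sus": sus,
            "self_report": self_report,
        }
    )
    out = pivot.index.to_frame(index=False)
    out["flagged"] = clauses.any(axis=1).to_numpy()
    out["clauses"] = [
        ",".join(name for name, fired in row.items() if fired)
        for _, row in clauses.iterrows()
    ]
    return out


@dataclass(frozen=True)
class CalibrationResult:
    """Per-group diffusion parameters estimated from stress flags."""

    per_group: pd.DataFrame  # group, n_subjects, adoption_fraction, imitation_effectiveness
    flag_counts: pd.DataFrame  # group, condition, n_flagged, n_subjects

    def params(self, group: str) -> tuple[float, float]:
        row = self.per_group.set_index("group").loc[group]
        return float(row["adoption_fraction"]), float(row["imitation_effectiveness"])


def estimate_parameters(flags: pd.DataFrame) -> CalibrationResult:
    """AdoptionFraction and ImitationEffectiveness per group from flags.

    AdoptionFraction is the proportion of subjects flagged in the cognitive
    stress task; ImitationEffectiveness is the mean over the four media
    conditions of the per-condition flagged proportion.
    """
    needed = set(MEDIA_CONDITIONS) | {TASK_CONDITION}
    present = set(flags["condition"].unique())
    if not needed <= present:
        raise ValueError(f"flags must cover conditions {sorted(needed)}")
    rows, counts = [], []
    for group, sub in flags.groupby("group", sort=True):
        n = sub["subject"].nunique()
        if n == 0:
            raise ValueError(f"empty group {group!r}")
        by_cond = sub.groupby("condition")["flagged"].agg(["sum", "count"])
        adoption = float(by_cond.loc[TASK_CONDITION, "sum"] / by_cond.loc[TASK_CONDITION, "count"])
        media_props = [
            float(by_cond.loc[c, "sum"] / by_cond.loc[c, "count"]) for c in MEDIA_CONDITIONS
        ]
        rows.append(
            {
                "group": group,
                "n_subjects": n,
                "adoption_fraction": adoption,
                "imitation_effectiveness": float(np.mean(media_props)),
            }
        )
        for cond in sorted(needed):
            counts.append(
                {
                    "group": group,
                    "condition": cond,
                    "n_flagged": int(by_cond.loc[cond, "sum"]),
                    "n_subjects": int(by_cond.loc[cond, "count"]),
                }
            )
    return CalibrationResult(per_group=pd.DataFrame(rows), flag_counts=pd.DataFrame(counts))


def threshold_sweep(
    table: pd.DataFrame, st_grid: Sequence[float], cfg: Optional[StressRuleConfig] = None
) -> pd.DataFrame:
    """Calibration parameters as functions of the stress threshold.

    Evaluates both parameters at every ST in ``st_grid``. Raising ST can
    only unflag records, so (with the presence clause disabled, which
    ignores ST) both curves are non-increasing in ST.
    """
    grid = np.asarray(st_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("st_grid must be non-empty")
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("st values must lie in [0, 1]")
    cfg = cfg or StressRuleConfig()
    deltas = compute_deltas(table)
    rows = []
    for st in grid:
        res = estimate_parameters(apply_stress_rule(deltas, replace(cfg, st=float(st))))
        for _, r in res.per_group.iterrows():
            rows.append(
                {
                    "st": float(st),
                    "group": r["group"],
                    "adoption_fraction": r["adoption_fraction"],
                    "imitation_effectiveness": r["imitation_effectiveness"],
                }
            )
    return pd.DataFrame(rows)
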
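"""Seeded synthetic cohorts of TUG-like tri-axial accelerometer recordings.

The clinical dataset this pipeline was designed around cannot be
redistributed, so this module generates a stand-in cohort with the two
properties every downstream stage needs:

* group-dependent signal complexity — each axis is a sum of gait
  harmonics (fundamental step frequency plus overtones, random phases)
  and spectrally shaped 1/f^beta Gaussian noise, with the healthy group
  using more correlated noise (larger beta) and the fall-risk group
  whiter noise, so multiscale entropy separates the groups for the
  classic white-vs-1/f reason;
* clinical scores coupled to group membership — TUG seconds, SFBBS
  points and SPMSQ errors are drawn from truncated distributions on
  either side of the published cut-offs, so the labeling rules recover
  the generator's ground truth exactly when score jitter is zero.

Group structure across tests follows a latent-frailty ranking: each
subject receives a frailty score, and for every test the required number
of fallers is taken from the top of that ranking.  Faller sets are
therefore nested across tests (matching the intersection pattern of
multifactor labels), and the recording's complexity group is "faller"
iff the subject is a faller on the most lenient single test.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import AXES, Recording
from .labeling import SINGLE_TESTS, ClinicalScores

HEALTHY = "healthy"
FALLER = "faller"

# Score distributions per group: (mean, sd, lower, upper), truncated so
# that without jitter every draw lands on the correct side of the cut-off.
_SCORE_DISTS = {
    "TUG": {HEALTHY: (9.5, 1.8, 4.0, 12.4), FALLER: (16.5, 2.5, 13.2, 30.0)},
    "BBS": {HEALTHY: (26.0, 2.0, 23.0, 28.0), FALLER: (18.0, 3.0, 0.0, 22.0)},
    "SPMSQ": {HEALTHY: (1.0, 1.0, 0.0, 2.0), FALLER: (5.0, 2.0, 3.0, 10.0)},
}


class InvalidSpecError(ValueError):
    """Raised when cohort-generation parameters are inconsistent."""


def _default_fractions() -> dict[str, float]:
    # default label imbalance for a 74-subject screening cohort
    return {"TUG": 17 / 74, "BBS": 13 / 74, "SPMSQ": 6 / 74}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Signal model per axis (amplitudes in g-units):

    * gait harmonics: sum over h = 1..n_harmonics of
      (harmonic_amplitude / h) * sin(2 pi h gait_frequency t + phase_h)
      with phases drawn uniformly per axis;
    * gait variability: 1/f^beta Gaussian noise band-limited to
      noise_band_limit_hz and scaled to SD noise_amplitude.  beta is a
      subject-level trait drawn from Normal(group mean, sd) truncated at
      0; healthy subjects get the larger (more correlated) exponent;
    * sensor noise: a white Gaussian floor of SD sensor_noise_amplitude,
      identical in distribution for every subject;
    * a static per-axis baseline offset Normal(0, baseline_offset_sd)
      modelling gravity leakage from imperfect sensor orientation.
    """

    n_subjects: int = 74
    faller_fraction_per_test: dict[str, float] = field(
        default_factory=_default_fractions)
    sampling_rate: float = 50.0
    duration: float = 30.0
    gait_frequency: float = 1.8
    n_harmonics: int = 3
    harmonic_amplitude: float = 0.15
    noise_amplitude: float = 0.4
    noise_band_limit_hz: float = 2.0
    sensor_noise_amplitude: float = 0.25
    noise_spectral_exponent_healthy: float = 1.5
    noise_spectral_exponent_faller: float = 0.0
    noise_spectral_exponent_sd: float = 0.2
    baseline_offset_sd: float = 0.1
    score_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidSpecError("n_subjects must be >= 2")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise InvalidSpecError("duration and sampling_rate must be positive")
        for test, frac in self.faller_fraction_per_test.items():
            if not 0 < frac < 1:
                raise InvalidSpecError(
                    f"faller fraction for {test} must be in (0,1), got {frac}")
        if self.n_harmonics >= 1 and self.sampling_rate <= (
                2 * self.gait_frequency * self.n_harmonics):
            raise InvalidSpecError(
                "sampling_rate must exceed twice the highest gait harmonic")

    @property
    def n_samples(self) -> int:
        return round(self.sampling_rate * self.duration)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SubjectRecord:
    """One synthetic subject: recording, scores and ground-truth groups."""

    subject_id: str
    recording: Recording
    scores: ClinicalScores
    true_group: dict[str, str]


def _colored_noise(n: int, beta: float, rng: np.random.Generator,
                   band_limit: float | None = None,
                   sampling_rate: float = 1.0) -> np.ndarray:
    """Unit-SD Gaussian noise with power spectrum proportional to 1/f^beta.

    With ``band_limit`` (Hz) the spectrum is truncated above that
    frequency, confining the process to the physiological movement band.
    """
    white = rng.standard_normal(n)
    if beta == 0 and band_limit is None:
        out = white
    else:
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
        gain = np.zeros_like(freqs)
        gain[1:] = freqs[1:] ** (-beta / 2)
        if band_limit is not None:
            gain[freqs > band_limit] = 0.0
        out = np.fft.irfft(spectrum * gain, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def simulate_recording(spec: CohortSpec, group: str,
                       rng: np.random.Generator) -> Recording:
    """One tri-axial recording for a subject of the given complexity group."""
    if group not in (HEALTHY, FALLER):
        raise InvalidSpecError(f"unknown group {group!r}")
    n = spec.n_samples
    t = np.arange(n) / spec.sampling_rate
    beta_mean = (spec.noise_spectral_exponent_healthy if group == HEALTHY
                 else spec.noise_spectral_exponent_faller)
    # the spectral exponent is a subject-level trait: one draw per
    # recording, shared by all axes, truncated at white noise (beta >= 0)
    beta = beta_mean
    if spec.noise_spectral_exponent_sd > 0:
        beta = max(0.0, rng.normal(beta_mean, spec.noise_spectral_exponent_sd))
    axes = {}
    for axis in AXES:
        signal = np.zeros(n)
        if spec.baseline_offset_sd > 0:
            # static gravity leakage from imperfect sensor orientation
            signal += rng.normal(0, spec.baseline_offset_sd)
        for h in range(1, spec.n_harmonics + 1):
            phase = rng.uniform(0, 2 * np.pi)
            signal += (spec.harmonic_amplitude / h) * np.sin(
                2 * np.pi * h * spec.gait_frequency * t + phase)
        if spec.noise_amplitude > 0:
            band = spec.noise_band_limit_hz if spec.noise_band_limit_hz else None
            signal = signal + spec.noise_amplitude * _colored_noise(
                n, beta, rng, band_limit=band,
                sampling_rate=spec.sampling_rate)
        if spec.sensor_noise_amplitude > 0:
            # white measurement-noise floor, identical across subjects
            signal = signal + spec.sensor_noise_amplitude * rng.standard_normal(n)
        axes[axis] = signal
    return Recording(axes=axes, sampling_rate=spec.sampling_rate)


def _truncnorm_draw(mean: float, sd: float, lo: float, hi: float,
                    rng: np.random.Generator) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_scores(groups: dict[str, str], jitter: float,
                 rng: np.random.Generator) -> ClinicalScores:
    raw = {}
    for test in SINGLE_TESTS:
        mean, sd, lo, hi = _SCORE_DISTS[test][
            FALLER if groups[test] == FALLER else HEALTHY]
        value = _truncnorm_draw(mean, sd, lo, hi, rng)
        if jitter > 0:
            value += rng.normal(0, jitter)
        raw[test] = value
    return ClinicalScores(
        tug_seconds=max(raw["TUG"], 0.1),
        sfbbs_points=int(np.clip(round(raw["BBS"]), 0, 28)),
        spmsq_errors=int(np.clip(round(raw["SPMSQ"]), 0, 10)),
    )


def simulate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full cohort deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    frailty = rng.random(n)
    order = np.argsort(frailty)  # ascending; fallers taken from the top

    faller_count = {}
    for test, frac in spec.faller_fraction_per_test.items():
        count = round(frac * n)
        if count < 1:
            warnings.warn(
                f"faller fraction {frac:.3g} for {test} yields an expected "
                f"count below 1 at n={n}; no fallers generated", stacklevel=2)
        faller_count[test] = count

    groups_per_subject: list[dict[str, str]] = [dict() for _ in range(n)]
    for test in SINGLE_TESTS:
        count = faller_count.get(test, 0)
        faller_idx = set(order[n - count:]) if count > 0 else set()
        for i in range(n):
            groups_per_subject[i][test] = (
                FALLER if i in faller_idx else HEALTHY)

    records = []
    width = len(str(n))
    for i in range(n):
        groups = groups_per_subject[i]
        # combined-test ground truth follows the intersection rule
        for a, b in (("TUG", "BBS"), ("TUG", "SPMSQ"), ("BBS", "SPMSQ")):
            groups[f"{a}+{b}"] = (FALLER if groups[a] == FALLER
                                  and groups[b] == FALLER else HEALTHY)
        signal_group = (FALLER if FALLER in
                        {groups[t] for t in SINGLE_TESTS} else HEALTHY)
        recording = simulate_recording(spec, signal_group, rng)
        scores = _draw_scores(groups, spec.score_noise_sd, rng)
        records.append(SubjectRecord(
            subject_id=f"S{i + 1:0{width}d}",
            recording=recording,
            scores=scores,
            true_group=groups,
        ))
    return records


def cohort_scores_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Per-subject clinical-score table (tug_seconds, sfbbs_points, spmsq_errors)."""
    table = pd.DataFrame(
        {
            "tug_seconds": [r.scores.tug_seconds for r in records],
            "sfbbs_points": [r.scores.sfbbs_points for r in records],
            "spmsq_errors": [r.scores.spmsq_errors for r in records],
        },
        index=[r.subject_id for r in records],
    )
    table.index.name = "subject_id"
    return table


def true_group_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Ground-truth 0/1 group table (1 = faller) for every test condition."""
    tests = list(records[0].true_group)
    table = pd.DataFrame(
        {t: [int(r.true_group[t] == FALLER) for r in records] for t in tests},
        index=[r.subject_id for r in records],
    )
    table.index.name = "subject_id"
    return table


def write_cohort(records: list[SubjectRecord], out_dir: str | Path,
                 spec: CohortSpec | None = None) -> Path:
    """Write a cohort as plain text: one CSV per recording, one score table.

    Each recording file has columns time_s, ml_g, v_g, ap_g with a header
    row; the cohort table is scores.csv; the generating spec (if given)
    is stored as spec.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_dir = out / "recordings"
    rec_dir.mkdir(exist_ok=True)
    for r in records:
        rec = r.recording
        t = np.arange(rec.n_samples) / rec.sampling_rate
        df = pd.DataFrame({
            "time_s": t,
            "ml_g": rec.axes["ML"],
            "v_g": rec.axes["V"],
            "ap_g": rec.axes["AP"],
        })
        df.to_csv(rec_dir / f"{r.subject_id}.csv", index=False)
    cohort_scores_table(records).to_csv(out / "scores.csv")
    if spec is not None:
        (out / "spec.json").write_text(json.dumps(spec.to_dict(), indent=2))
    return out


def read_recording(path: str | Path,
                   sampling_rate: float | None = None) -> Recording:
    """Read one recording CSV (time_s, ml_g, v_g, ap_g) back into memory.

    The sampling rate is inferred from the time column unless given.
    """
    df = pd.read_csv(path)
    if sampling_rate is None:
        if "time_s" not in df.columns or len(df) < 2:
            raise InvalidSpecError(
                f"{path}: cannot infer sampling rate without a time_s column")
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        sampling_rate = 1.0 / dt
    return Recording(
        axes={"ML": df["ml_g"].to_numpy(),
              "V": df["v_g"].to_numpy(),
              "AP": df["ap_g"].to_numpy()},
        sampling_rate=sampling_rate,
    )


def read_cohort_dir(path: str | Path) -> dict[str, Recording]:
    """Read every recording CSV under ``path``/recordings (or ``path`` itself)."""
    base = Path(path)
    rec_dir = base / "recordings" if (base / "recordings").is_dir() else base
    recordings = {}
    for f in sorted(rec_dir.glob("*.csv")):
        recordings[f.stem] = read_recording(f)
    if not recordings:
        raise InvalidSpecError(f"no recording CSV files found under {rec_dir}")
    return recordings
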
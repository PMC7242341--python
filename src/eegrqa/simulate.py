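"""Synthetic 19-channel EEG cohorts with a region-localized complexity deficit.

Each channel is a standardized mixture

    x = (1 - w) * colored_noise(beta) + w * quasi-periodic oscillation

scaled to EEG-like microvolt amplitude. The colored noise has a 1/f^beta
spectrum (beta = 1 approximates background EEG); the oscillation is a sine
at ``osc_freq_hz`` with random-walk phase jitter so its recurrence
structure is quasi- rather than strictly periodic. Raising the mixing
weight w makes the signal more regular — lower sample entropy, longer
recurrence lines — so w is the generative "complexity knob".

Case subjects receive ``osc_mix + ct_deficit`` on centrotemporal channels
and ``osc_mix`` elsewhere; contrast subjects receive ``osc_mix``
everywhere. The injected ground truth is therefore the *location and
direction* of a complexity deficit, not a target value of any measure.
Per-channel weight jitter models electrode-level variability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Recording, write_edf_recording
from .montage import CT_SENSORS, STANDARD_1020


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate a small clinical study: two cohorts of 10, one-minute
    19-channel recordings at 256 Hz, pink-noise background with a mild
    9 Hz (alpha-range) oscillatory component, and an extra 0.3 mixing
    weight on centrotemporal channels of case subjects only.
    """

    n_case: int = 10
    n_contrast: int = 10
    fs: float = 256.0
    duration_s: float = 60.0
    base_spectral_exponent: float = 1.0
    osc_mix: float = 0.1
    ct_deficit: float = 0.3
    osc_freq_hz: float = 9.0
    jitter_sd: float = 0.02
    seed: int = 0
    amplitude_uv: float = 20.0
    phase_jitter_sd: float = 0.05  # radians per sample

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_contrast < 1:
            raise ValueError("need at least one subject per group")
        if not 0 <= self.osc_mix < 1:
            raise ValueError("osc_mix must lie in [0, 1)")
        if self.osc_mix + self.ct_deficit + 5 * self.jitter_sd >= 1:
            raise ValueError("osc_mix + ct_deficit + jitter bound must stay below 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticCohortSpec":
        return cls(**json.loads(Path(path).read_text()))


def colored_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^beta noise, synthesized in the frequency domain."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2)
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    x -= x.mean()
    return x / x.std()


def jittered_oscillation(
    n: int, fs: float, freq_hz: float, rng: np.random.Generator,
    phase_jitter_sd: float = 0.05,
) -> np.ndarray:
    """Unit-variance sine with random-walk phase noise (quasi-periodic)."""
    phase = 2 * np.pi * freq_hz * np.arange(n) / fs
    phase = phase + np.cumsum(rng.normal(0.0, phase_jitter_sd, n))
    x = np.sin(phase)
    x -= x.mean()
    return x / x.std()


def generate_channel_signal(
    fs: float,
    duration_s: float,
    beta: float,
    mix_weight: float,
    osc_freq_hz: float,
    rng: np.random.Generator,
    phase_jitter_sd: float = 0.05,
) -> np.ndarray:
    """One standardized channel: (1-w) * noise + w * quasi-periodic sine."""
    if not 0 <= mix_weight < 1:
        raise ValueError(f"mix weight must lie in [0, 1), got {mix_weight}")
    n = int(round(fs * duration_s))
    noise = colored_noise(n, beta, rng)
    if mix_weight == 0:
        return noise
    osc = jittered_oscillation(n, fs, osc_freq_hz, rng, phase_jitter_sd)
    return (1 - mix_weight) * noise + mix_weight * osc


def generate_cohort(
    spec: SyntheticCohortSpec, out_dir: str | Path | None = None
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate all recordings of a cohort; optionally write EDFs + manifest.

    Deterministic: the same spec (seed included) yields byte-identical EDF
    files and manifest. When ``out_dir`` is given, EDFs are written with
    clinical-style labels ("EEG C3-REF") and a ``manifest.csv`` referencing
    them is created.
    """
    rng = np.random.default_rng(spec.seed)
    recordings: list[Recording] = []
    rows = []
    subjects = [("case", i) for i in range(spec.n_case)] + [
        ("contrast", i) for i in range(spec.n_contrast)
    ]
    for group, i in subjects:
        subject_id = f"{group}_{i + 1:02d}"
        data = np.empty((len(STANDARD_1020), int(round(spec.fs * spec.duration_s))))
        for c, ch in enumerate(STANDARD_1020):
            base = spec.osc_mix
            if group == "case" and ch in CT_SENSORS:
                base += spec.ct_deficit
            w = float(np.clip(base + rng.normal(0.0, spec.jitter_sd), 0.0, 0.99))
            data[c] = spec.amplitude_uv * generate_channel_signal(
                spec.fs, spec.duration_s, spec.base_spectral_exponent,
                w, spec.osc_freq_hz, rng, spec.phase_jitter_sd,
            )
        rec = Recording(
            subject_id=subject_id, group=group, fs=spec.fs,
            channels=list(STANDARD_1020), data=data,
        )
        recordings.append(rec)
        rows.append((subject_id, group, f"{subject_id}.edf"))
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "edf_path"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, (_, _, fname) in zip(recordings, rows):
            write_edf_recording(rec, out_dir / fname, raw_label_style="clinical")
        manifest.to_csv(out_dir / "manifest.csv", index=False, lineterminator="\n")
        spec.to_json(out_dir / "cohort_spec.json")
    return recordings, manifest


def calibrate_complexity_knob(
    spec: SyntheticCohortSpec,
    measures: tuple[str, ...] = ("SampE", "DET"),
    weights: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8),
    n_seeds: int = 20,
    banded: bool = False,
) -> pd.DataFrame:
    """Sweep mixing weight -> mean measure value (the knob's dose-response).

    Uses the pipeline's own estimators as measuring devices, so the table
    reflects exactly what the analysis will see. With ``banded=True`` the
    device is the pipeline's full multiscale reduction — the measure is
    computed per wavelet band and collapsed to the area under the
    multiscale curve — which is what the region statistics consume; this
    is how tests obtain the expected *direction* of an injected contrast
    per measure. Reproducible for a fixed spec seed.
    """
    from .bands import wavelet_band_decompose
    from .entropy import SampEnConfig, sample_entropy
    from .rqa import RecurrenceConfig, rqa_from_signal
    from .stats import curve_auc

    rng = np.random.default_rng(spec.seed)
    sampen_cfg = SampEnConfig()
    rqa_cfg = RecurrenceConfig()

    def measure_signal(x: np.ndarray, measure: str) -> float:
        if measure == "SampE":
            return sample_entropy(x, sampen_cfg)
        return getattr(rqa_from_signal(x, rqa_cfg), measure)

    # common random numbers: every weight sees the same noise and oscillation
    # realizations, so the dose-response is a paired contrast and the sweep's
    # shape is not masked by between-signal variance
    child_seeds = rng.integers(0, 2 ** 31, size=n_seeds)
    per: dict[tuple[float, str], list[float]] = {
        (w, m): [] for w in weights for m in measures
    }
    for child in child_seeds:
        for w in weights:
            x = generate_channel_signal(
                spec.fs, spec.duration_s, spec.base_spectral_exponent,
                w, spec.osc_freq_hz, np.random.default_rng(child),
                spec.phase_jitter_sd,
            )
            if banded:
                bandset = wavelet_band_decompose(x, spec.fs)
                for m in measures:
                    vals = np.array([measure_signal(b.signal, m) for b in bandset])
                    per[(w, m)].append(curve_auc(vals))
            else:
                for m in measures:
                    per[(w, m)].append(measure_signal(x, m))
    rows = [
        (w, m, float(np.nanmean(per[(w, m)])), n_seeds)
        for w in weights for m in measures
    ]
    return pd.DataFrame(rows, columns=["mix_weight", "measure", "mean_value", "n_seeds"])


def injected_auc_direction(
    spec: SyntheticCohortSpec, measure: str = "SampE", n_seeds: int = 12
) -> int:
    """Sign (+1/-1) of the banded-AUC shift the CT deficit injects.

    Compares the knob's banded-AUC dose-response at the two weights the
    cohort actually uses: the baseline ``osc_mix`` and the case-CT weight
    ``osc_mix + ct_deficit``.
    """
    table = calibrate_complexity_knob(
        spec, measures=(measure,),
        weights=(spec.osc_mix, spec.osc_mix + spec.ct_deficit),
        n_seeds=n_seeds, banded=True,
    )
    lo = table.loc[table["mix_weight"] == spec.osc_mix, "mean_value"].iloc[0]
    hi = table.loc[
        table["mix_weight"] == spec.osc_mix + spec.ct_deficit, "mean_value"
    ].iloc[0]
    return 1 if hi >= lo else -1
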
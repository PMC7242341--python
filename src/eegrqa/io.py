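"""EDF I/O, cohort manifests and random segment selection.

Recordings are kept in microvolts as a channels x samples matrix. Reading
goes through :mod:`mne`; a small writer for plain EDF (16-bit, 1-second
data records) is provided so synthetic cohorts round-trip through the same
clinical file format real data arrives in. No filtering or artifact
processing is applied anywhere on the read path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import DEFAULT_MONTAGE, Montage

logger = logging.getLogger(__name__)

GROUPS = ("case", "contrast")


@dataclass
class Recording:
    """A multichannel EEG recording in physical units (microvolts)."""

    subject_id: str
    group: str
    fs: float
    channels: list[str]
    data: np.ndarray  # channels x samples, microvolts

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.channels)} channel labels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels not unique after normalization")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment:
    """A fixed-duration excerpt of a recording, with provenance."""

    recording_ref: str
    group: str
    fs: float
    start_sample: int
    duration_s: float
    channels: list[str]
    data: np.ndarray
    selection_seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n_expected = self.duration_s * self.fs
        if abs(n_expected - round(n_expected)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer number of samples")
        if self.data.shape != (len(self.channels), int(round(n_expected))):
            raise ValueError("segment data shape inconsistent with duration and channels")


# ---------------------------------------------------------------------------
# EDF header inspection (labels + per-signal rates) and the minimal writer.
# mne reads EDF but silently reconciles mixed per-channel sampling rates, and
# no installed library writes EDF, hence the two small routines below.
# ---------------------------------------------------------------------------

def _edf_signal_headers(path: str | Path) -> tuple[int, float, list[dict]]:
    """Parse the EDF fixed + signal headers. Returns (n_records, record_s, signals)."""
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise OSError(f"{path}: truncated EDF header")
        try:
            n_records = int(fixed[236:244].decode("ascii").strip())
            record_s = float(fixed[244:252].decode("ascii").strip())
            ns = int(fixed[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise OSError(f"{path}: malformed EDF header: {exc}") from exc
        raw = fh.read(ns * 256)
        if len(raw) < ns * 256:
            raise OSError(f"{path}: truncated EDF signal headers")

    def fields(offset: int, width: int) -> list[str]:
        base = offset * ns
        return [
            raw[base + i * width: base + (i + 1) * width].decode("ascii", "replace").strip()
            for i in range(ns)
        ]

    # signal header layout: label 16, transducer 80, dim 8, phys min/max 8+8,
    # dig min/max 8+8, prefiltering 80, samples-per-record 8 (column-major)
    labels = fields(0, 16)
    dims = [raw[ns * 96 + i * 8: ns * 96 + (i + 1) * 8].decode("ascii", "replace").strip()
            for i in range(ns)]
    spr_base = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = [int(raw[spr_base + i * 8: spr_base + (i + 1) * 8].decode("ascii").strip())
           for i in range(ns)]
    signals = [
        {"label": lab, "dimension": dim, "samples_per_record": n}
        for lab, dim, n in zip(labels, dims, spr)
    ]
    return n_records, record_s, signals


def read_edf_recording(
    path: str | Path,
    subject_id: str,
    group: str,
    montage: Montage = DEFAULT_MONTAGE,
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` in microvolts.

    Channel labels are normalized onto the 10-20 montage nomenclature;
    annotation channels are dropped; each channel's stored physical
    calibration is honoured. Channels with differing sampling rates are
    rejected rather than resampled.
    """
    import mne

    path = Path(path)
    if not path.is_file():
        raise OSError(f"EDF file not found: {path}")
    try:
        n_records, record_s, signals = _edf_signal_headers(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read EDF file {path}: {exc}") from exc

    data_signals = [s for s in signals if s["label"] != "EDF Annotations"]
    if not data_signals:
        raise OSError(f"{path}: no signal channels")
    rates = {s["samples_per_record"] / record_s for s in data_signals}
    if len(rates) > 1:
        raise ValueError(
            f"{path}: channels have differing sampling rates {sorted(rates)} Hz; "
            "resampling is not performed"
        )

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of types for corrupt files
        raise OSError(f"cannot read EDF file {path}: {exc}") from exc
    picks = [i for i, ch in enumerate(raw.ch_names) if ch != "EDF Annotations"]
    labels = [montage.normalize(raw.ch_names[i]) for i in picks]
    # mne scales recognized physical dimensions to SI (volts for uV/mV inputs)
    data_uv = raw.get_data(picks=picks) * 1e6
    return Recording(
        subject_id=subject_id,
        group=group,
        fs=float(raw.info["sfreq"]),
        channels=labels,
        data=data_uv,
    )


def write_edf_recording(rec: Recording, path: str | Path, raw_label_style: str = "plain") -> Path:
    """Write a :class:`Recording` as a plain EDF file (16-bit, 1-s records).

    ``raw_label_style="clinical"`` writes labels as ``"EEG <name>-REF"`` to
    mimic clinical exports and exercise label normalization on re-read.
    The start date/time is fixed so identical data yields identical bytes.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape
    if n_samp % fs != 0:
        raise ValueError("EDF writer requires a whole number of 1-second records")
    n_records = n_samp // fs

    labels = [
        f"EEG {ch}-REF" if raw_label_style == "clinical" else ch for ch in rec.channels
    ]
    # per-channel symmetric physical range with headroom keeps the 16-bit
    # quantization error small relative to the signal
    phys_max = np.maximum(np.abs(rec.data).max(axis=1) * 1.05, 1e-3)
    dig_min, dig_max = -32768, 32767

    header = b""
    header += b"0".ljust(8)
    header += rec.subject_id.encode("ascii", "replace")[:80].ljust(80)
    header += f"Startdate 01-JAN-2000 {rec.group}".encode()[:80].ljust(80)
    header += b"01.01.00"
    header += b"00.00.00"
    header += str(256 * (1 + n_ch)).encode().ljust(8)
    header += b"".ljust(44)
    header += str(n_records).encode().ljust(8)
    header += b"1".ljust(8)
    header += str(n_ch).encode().ljust(4)

    def col(values: list[str], width: int) -> bytes:
        out = b""
        for v in values:
            b = v.encode("ascii", "replace")[:width]
            out += b.ljust(width)
        return out

    header += col(labels, 16)
    header += col([""] * n_ch, 80)                       # transducer
    header += col(["uV"] * n_ch, 8)                      # physical dimension
    header += col([f"{-m:.6g}"[:8] for m in phys_max], 8)
    header += col([f"{m:.6g}"[:8] for m in phys_max], 8)
    header += col([str(dig_min)] * n_ch, 8)
    header += col([str(dig_max)] * n_ch, 8)
    header += col([""] * n_ch, 80)                       # prefiltering
    header += col([str(fs)] * n_ch, 8)
    header += col([""] * n_ch, 32)                       # reserved

    # quantize with the exact gains implied by the header strings
    pmaxs = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    pmins = -pmaxs
    gain = (dig_max - dig_min) / (pmaxs - pmins)
    digital = np.rint((rec.data - pmins[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())  # C-order: channel by channel
    return path


# ---------------------------------------------------------------------------
# Manifests and segment selection
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("subject_id", "group", "edf_path")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (``subject_id,group,edf_path``).

    Relative EDF paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"manifest {path} has invalid group labels {sorted(bad)}")
    df["edf_path"] = [
        str(p if Path(p).is_absolute() else path.parent / p) for p in df["edf_path"]
    ]
    return df[list(MANIFEST_COLUMNS)]


def select_awake_segment(
    rec: Recording,
    duration_s: float = 30.0,
    seed: int = 0,
    amplitude_veto_uv: float | None = None,
) -> Segment:
    """Randomly select a fixed-duration segment from a recording.

    Candidate start positions lie on a 1-second grid in
    ``[0, T - duration_s]`` and one is drawn uniformly with a seeded
    generator, so selection is reproducible. With ``amplitude_veto_uv``
    set, candidates containing any sample beyond the threshold are skipped
    (in seeded random order); if every candidate fails the veto the first
    drawn candidate is used with a warning. No filtering is applied.
    """
    n_needed = duration_s * rec.fs
    if abs(n_needed - round(n_needed)) > 1e-9:
        raise ValueError("duration_s * fs must be an integer number of samples")
    n_needed = int(round(n_needed))
    if n_needed > rec.n_samples:
        raise ValueError(
            f"recording {rec.subject_id} has {rec.duration_s:.1f} s, "
            f"{duration_s:.1f} s required"
        )
    fs_int = rec.fs
    step = int(round(fs_int))  # 1-second grid
    max_start = rec.n_samples - n_needed
    candidates = np.arange(0, max_start + 1, step)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    chosen = candidates[order[0]]
    if amplitude_veto_uv is not None:
        for idx in order:
            start = candidates[idx]
            window = rec.data[:, start:start + n_needed]
            if np.abs(window).max() <= amplitude_veto_uv:
                chosen = start
                break
        else:
            logger.warning(
                "subject %s: no candidate window passes the +/-%g uV veto; "
                "using an unvetoed window", rec.subject_id, amplitude_veto_uv,
            )
    return Segment(
        recording_ref=rec.subject_id,
        group=rec.group,
        fs=rec.fs,
        start_sample=int(chosen),
        duration_s=duration_s,
        channels=list(rec.channels),
        data=rec.data[:, chosen:chosen + n_needed].copy(),
        selection_seed=seed,
    )
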
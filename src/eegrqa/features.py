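"""Per-segment feature extraction: sensors x bands x nonlinear measures.

Produces the long-format feature table every downstream statistic consumes:
one row per (subject, sensor, band, measure) with columns

    subject_id, group, sensor, region, band_index, band_low_hz,
    band_high_hz, measure, value

Undefined measures are recorded as NaN (empty field in CSV) with the reason
logged — never silently as zero, which would bias area-under-curve
statistics downward. A failure in one band never aborts the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import DEFAULT_LEVELS, DEFAULT_WAVELET, wavelet_band_decompose
from .entropy import SampEnConfig, dfa_alpha, sample_entropy
from .io import Segment
from .montage import DEFAULT_MONTAGE, Montage
from .rqa import RecurrenceConfig, rqa_from_signal

logger = logging.getLogger(__name__)

CORE_MEASURES = ("SampE", "TT", "Lmax", "Lmean")
RQA_MEASURES = ("TT", "Lmax", "Lmean", "DET", "LAM", "RR")
ALL_MEASURES = ("SampE",) + RQA_MEASURES + ("DFA",)

FEATURE_COLUMNS = (
    "subject_id", "group", "sensor", "region", "band_index",
    "band_low_hz", "band_high_hz", "measure", "value",
)


@dataclass(frozen=True)
class BandsConfig:
    wavelet: str = DEFAULT_WAVELET
    levels: int = DEFAULT_LEVELS


@dataclass(frozen=True)
class FeatureConfig:
    bands: BandsConfig = field(default_factory=BandsConfig)
    rqa: RecurrenceConfig = field(default_factory=RecurrenceConfig)
    sampen: SampEnConfig = field(default_factory=SampEnConfig)
    measures: tuple[str, ...] = CORE_MEASURES

    def __post_init__(self) -> None:
        unknown = set(self.measures) - set(ALL_MEASURES)
        if unknown:
            raise ValueError(f"unknown measures {sorted(unknown)}; known: {ALL_MEASURES}")


def features_for_segment(
    seg: Segment,
    config: FeatureConfig = FeatureConfig(),
    montage: Montage = DEFAULT_MONTAGE,
) -> pd.DataFrame:
    """Compute every requested measure on every sensor x frequency band.

    Only channels belonging to the montage are analyzed; others are skipped
    with a log message. Deterministic: no randomness downstream of segment
    selection.
    """
    rows: list[tuple] = []
    want_rqa = [m for m in config.measures if m in RQA_MEASURES]
    for ch_idx, sensor in enumerate(seg.channels):
        if sensor not in montage.all_sensors:
            logger.info("skipping non-montage channel %r", sensor)
            continue
        region = "CT" if sensor in montage.ct_sensors else "nonCT"
        bandset = wavelet_band_decompose(
            seg.data[ch_idx], seg.fs, config.bands.wavelet, config.bands.levels
        )
        for band in bandset:
            values: dict[str, float] = {}
            if "SampE" in config.measures:
                values["SampE"] = _safe(
                    sample_entropy, band.signal, config.sampen,
                    what=f"SampE {seg.recording_ref}/{sensor}/band{band.index}",
                )
            if want_rqa:
                res = rqa_from_signal(band.signal, config.rqa)
                for m in want_rqa:
                    values[m] = getattr(res, m)
            if "DFA" in config.measures:
                values["DFA"] = _safe(
                    dfa_alpha, band.signal,
                    what=f"DFA {seg.recording_ref}/{sensor}/band{band.index}",
                )
            for measure in config.measures:
                rows.append((
                    seg.recording_ref, seg.group, sensor, region, band.index,
                    band.low_hz, band.high_hz, measure, values[measure],
                ))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def _safe(fn, *args, what: str) -> float:
    try:
        return fn(*args)
    except ValueError as exc:
        logger.warning("%s undefined: %s", what, exc)
        return float("nan")


def write_feature_table(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path} missing columns {sorted(missing)}")
    return df
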
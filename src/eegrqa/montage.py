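"""Standard 10-20 scalp montage: label normalization and region classification.

The 19-electrode 10-20 montage is the clinical standard for routine scalp
EEG. Focal epilepsies of the Rolandic type localize to the centrotemporal
electrodes (C3, C4, Cz, T7, T8, P7, P8), so sensors are partitioned into a
centrotemporal (CT) set and the remaining non-CT set for region statistics.

Clinical EDF exports label channels inconsistently ("EEG C3-REF", "cz",
"T3"...); :func:`normalize_channel_label` maps them onto canonical modern
10-20 names, including the legacy T3/T4/T5/T6 -> T7/T8/P7/P8 renaming.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

#: The 19 electrodes of the standard 10-20 montage, front to back.
STANDARD_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

#: Centrotemporal electrodes (the Rolandic / epileptogenic zone).
CT_SENSORS: frozenset[str] = frozenset({"C3", "C4", "Cz", "T7", "T8", "P7", "P8"})

#: Legacy 10-20 names (pre-1991 nomenclature) -> modern names.
LEGACY_ALIASES: dict[str, str] = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

_CANONICAL = {label.upper(): label for label in STANDARD_1020}
_ALIASES_UPPER = {k.upper(): v for k, v in LEGACY_ALIASES.items()}
_REFERENCE_SUFFIXES = ("-REF", "-LE", "-A1", "-A2")


def normalize_channel_label(raw: str) -> str:
    """Normalize a raw EDF channel label to a canonical 10-20 name.

    Strips an ``"EEG "`` prefix and reference suffixes (``-REF``, ``-LE``,
    ``-A1``, ``-A2``), fixes case, and maps legacy aliases (T3->T7 etc.).
    Labels that are not 10-20 electrode names (e.g. ``"ECG"``) pass through
    stripped but otherwise unchanged; they are excluded downstream when the
    montage is enforced.
    """
    label = raw.strip()
    if label.upper().startswith("EEG "):
        label = label[4:].strip()
    for suffix in _REFERENCE_SUFFIXES:
        if label.upper().endswith(suffix):
            label = label[: -len(suffix)].strip()
            break
    key = label.upper()
    if key in _ALIASES_UPPER:
        return _ALIASES_UPPER[key]
    return _CANONICAL.get(key, label)


@dataclass(frozen=True)
class Montage:
    """A sensor montage with a centrotemporal subset.

    Parameters
    ----------
    all_sensors
        Ordered electrode labels (19 for the standard 10-20 montage).
    ct_sensors
        Subset of ``all_sensors`` classified as centrotemporal.
    alias_map
        Extra raw-label -> normalized-label aliases applied on top of the
        built-in rules.
    """

    all_sensors: tuple[str, ...] = STANDARD_1020
    ct_sensors: frozenset[str] = CT_SENSORS
    alias_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.ct_sensors) <= set(self.all_sensors):
            extra = set(self.ct_sensors) - set(self.all_sensors)
            raise ValueError(f"ct_sensors not a subset of all_sensors: {sorted(extra)}")
        if len(set(self.all_sensors)) != len(self.all_sensors):
            raise ValueError("duplicate sensor labels in montage")

    def normalize(self, raw: str) -> str:
        label = self.alias_map.get(raw.strip(), raw)
        return normalize_channel_label(label)

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        """Load a montage override: ``{"ct_sensors": [...], "aliases": {...}}``."""
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            all_sensors=tuple(obj.get("all_sensors", STANDARD_1020)),
            ct_sensors=frozenset(obj.get("ct_sensors", CT_SENSORS)),
            alias_map=dict(obj.get("aliases", {})),
        )


DEFAULT_MONTAGE = Montage()


def classify_sensor_region(label: str, montage: Montage = DEFAULT_MONTAGE) -> str:
    """Classify a normalized sensor label as ``"CT"`` or ``"nonCT"``.

    Raises
    ------
    ValueError
        If ``label`` is not part of the montage.
    """
    if label not in montage.all_sensors:
        raise ValueError(f"sensor {label!r} is not in the montage")
    return "CT" if label in montage.ct_sensors else "nonCT"
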
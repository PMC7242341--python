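"""Group-level statistics: multiscale curves, AUC reduction, region ANOVA.

A multiscale curve is the per-band mean of one measure at one sensor across
the subjects of one group, with 95% confidence bands. Curves are reduced to
a single area-under-curve (AUC) value per subject x sensor (trapezoid over
band index with unit spacing), those observations are pooled into four
(group x region) cells, and a classical one-way ANOVA tests the effect of
cell on AUC.

Note the deliberate pseudo-replication: the ANOVA treats every
subject x sensor AUC as an independent observation although sensors within
a subject are correlated. This mirrors the study design it reproduces
(df_between = 3 over many observations) and is flagged as a caveat rather
than corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import DEFAULT_MONTAGE, Montage

logger = logging.getLogger(__name__)

CELLS = (("case", "CT"), ("case", "nonCT"), ("contrast", "CT"), ("contrast", "nonCT"))


@dataclass(frozen=True)
class MultiscaleCurve:
    measure: str
    sensor: str
    group: str
    band_means: np.ndarray
    ci_half_width: np.ndarray
    n_per_band: np.ndarray


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float
    ss_total: float


@dataclass(frozen=True)
class RegionSummary:
    measure: str
    cells: dict[tuple[str, str], np.ndarray]
    cell_means: dict[tuple[str, str], float]
    anova: AnovaResult


def multiscale_group_curve(
    table: pd.DataFrame,
    measure: str,
    sensor: str,
    group: str,
    ci_method: str = "normal",
) -> MultiscaleCurve:
    """Per-band mean and 95% CI of one measure at one sensor for one group.

    ``ci_method="normal"`` uses 1.96 * SEM; ``"t"`` uses the t quantile
    with n-1 degrees of freedom. A band with a single observation gets a
    zero half-width with a logged warning; a band with none is an error.
    """
    sub = table[
        (table["measure"] == measure)
        & (table["sensor"] == sensor)
        & (table["group"] == group)
    ]
    if sub.empty:
        raise ValueError(f"no rows for measure={measure!r} sensor={sensor!r} group={group!r}")
    band_indices = np.sort(table["band_index"].unique())
    means, hws, ns = [], [], []
    empty_bands = []
    for b in band_indices:
        vals = sub.loc[sub["band_index"] == b, "value"].dropna().to_numpy()
        n = len(vals)
        if n == 0:
            empty_bands.append(int(b))
            means.append(np.nan), hws.append(np.nan), ns.append(0)
            continue
        means.append(vals.mean())
        ns.append(n)
        if n == 1:
            logger.warning(
                "%s/%s/%s band %d: single observation, CI half-width set to 0",
                measure, sensor, group, b,
            )
            hws.append(0.0)
        else:
            sem = vals.std(ddof=1) / np.sqrt(n)
            z = 1.96 if ci_method == "normal" else float(sps.t.ppf(0.975, n - 1))
            hws.append(z * sem)
    if empty_bands:
        raise ValueError(
            f"{measure}/{sensor}/{group}: no observations in bands {empty_bands}"
        )
    return MultiscaleCurve(
        measure=measure, sensor=sensor, group=group,
        band_means=np.array(means), ci_half_width=np.array(hws),
        n_per_band=np.array(ns, dtype=int),
    )


def curve_auc(values: np.ndarray) -> float:
    """Trapezoidal area under a multiscale curve over band index (unit spacing).

    Interior missing values are linearly interpolated; missing end bands
    truncate the curve with a warning. Fewer than 2 non-missing values is
    an error.
    """
    v = np.asarray(values, dtype=float)
    finite = np.flatnonzero(np.isfinite(v))
    if len(finite) < 2:
        raise ValueError("curve_auc needs at least 2 non-missing band values")
    lo, hi = finite[0], finite[-1]
    if lo > 0 or hi < len(v) - 1:
        logger.warning(
            "curve truncated to bands [%d, %d] (missing terminal values)", lo, hi
        )
    idx = np.arange(lo, hi + 1)
    seg = v[lo:hi + 1]
    nan = ~np.isfinite(seg)
    if nan.any():
        seg = seg.copy()
        seg[nan] = np.interp(idx[nan], idx[~nan], seg[~nan])
    return float(np.trapezoid(seg, idx))


def subject_sensor_auc(
    table: pd.DataFrame, measure: str, montage: Montage = DEFAULT_MONTAGE
) -> pd.DataFrame:
    """Per (subject, sensor) AUC observations: the ANOVA's unit of analysis."""
    sub = table[table["measure"] == measure]
    if sub.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    rows = []
    for (subject, sensor), grp in sub.groupby(["subject_id", "sensor"], sort=True):
        grp = grp.sort_values("band_index")
        try:
            auc = curve_auc(grp["value"].to_numpy())
        except ValueError as exc:
            logger.warning("AUC undefined for %s/%s: %s", subject, sensor, exc)
            auc = np.nan
        rows.append((
            subject, grp["group"].iloc[0], sensor, grp["region"].iloc[0], auc,
        ))
    return pd.DataFrame(rows, columns=["subject_id", "group", "sensor", "region", "auc"])


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = sum(len(g) for g in groups)
    if n <= k:
        raise ValueError("not enough observations for within-group variance")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = sum(((g - grand) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        raise ValueError("zero within-group variance everywhere: F undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        F=float(f), df_between=df_b, df_within=df_w, p=p,
        ss_between=float(ss_between), ss_within=float(ss_within),
        ss_total=float(ss_total),
    )


def region_anova(
    table: pd.DataFrame,
    measure: str,
    montage: Montage = DEFAULT_MONTAGE,
    bonferroni_k: int = 1,
) -> RegionSummary:
    """One-way ANOVA of per-observation AUC over the four (group, region) cells."""
    auc = subject_sensor_auc(table, measure, montage).dropna(subset=["auc"])
    cells: dict[tuple[str, str], np.ndarray] = {}
    for cell in CELLS:
        vals = auc.loc[
            (auc["group"] == cell[0]) & (auc["region"] == cell[1]), "auc"
        ].to_numpy()
        if len(vals) == 0:
            raise ValueError(f"empty cell {cell}")
        cells[cell] = vals
    anova = one_way_anova([cells[c] for c in CELLS])
    if bonferroni_k > 1:
        anova = AnovaResult(
            F=anova.F, df_between=anova.df_between, df_within=anova.df_within,
            p=min(1.0, anova.p * bonferroni_k),
            ss_between=anova.ss_between, ss_within=anova.ss_within,
            ss_total=anova.ss_total,
        )
    cell_means = {c: float(v.mean()) for c, v in cells.items()}
    return RegionSummary(measure=measure, cells=cells, cell_means=cell_means, anova=anova)


def heatmap_table(
    table: pd.DataFrame,
    measure: str,
    montage: Montage = DEFAULT_MONTAGE,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Mean AUC per sensor and group (the scalp-heatmap values), 19 x 2 rows."""
    auc = subject_sensor_auc(table, measure, montage).dropna(subset=["auc"])
    rows = []
    for group in ("case", "contrast"):
        for sensor in montage.all_sensors:
            vals = auc.loc[
                (auc["group"] == group) & (auc["sensor"] == sensor), "auc"
            ].to_numpy()
            if len(vals) == 0:
                if allow_missing:
                    logger.warning("no AUC for sensor %s in group %s", sensor, group)
                    continue
                raise ValueError(f"no AUC observations for sensor {sensor} in group {group}")
            region = "CT" if sensor in montage.ct_sensors else "nonCT"
            rows.append((sensor, region, group, float(vals.mean()), len(vals)))
    return pd.DataFrame(rows, columns=["sensor", "region", "group", "mean_auc", "n"])
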
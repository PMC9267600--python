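"""Caliper-based xenograft tumour volumes, growth curves and endpoint effects.

Subcutaneous tumours are measured with calipers along two perpendicular axes.
The volume is estimated from the weighted mean diameter, shorter axis counted
twice:

    V = (π/6) · ((2·shorter + longer) / 3)³

which reduces exactly to the sphere volume when the two diameters agree.
Diameters are in mm, volumes in mm³.  Endpoint treatment effects
``E = 1 − treated/control`` on final mean volume (or weight) feed the
combination-index analysis of the in vivo arms.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "tumour_volume",
    "load_caliper_table",
    "growth_summary",
    "endpoint_summary",
    "in_vivo_effect",
    "treatment_effects",
    "xeno_viability",
]


def tumour_volume(shorter_mm, longer_mm):
    """Tumour volume in mm³ from two perpendicular caliper diameters in mm.

    Vectorized over array inputs.  Raises on nonpositive diameters; the
    arguments are used as given (swap-correction on ingest is the loader's
    job), though the formula is insensitive only up to the 2:1 weighting.
    """
    s = np.asarray(shorter_mm, dtype=float)
    l = np.asarray(longer_mm, dtype=float)
    if np.any(s <= 0) or np.any(l <= 0):
        raise ValueError("diameters must be positive")
    v = (math.pi / 6.0) * ((2.0 * s + l) / 3.0) ** 3
    return float(v) if v.ndim == 0 else v


def load_caliper_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a caliper table and derive volumes.

    Expected columns: ``animal_id, group, day, shorter_mm, longer_mm`` and
    optionally ``weight_g``.  Measurements where the recorded shorter
    diameter exceeds the longer one are swap-corrected.
    """
    needed = {"animal_id", "group", "day", "shorter_mm", "longer_mm"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"caliper table is missing columns: {sorted(missing)}")
    out = df.copy()
    s = out["shorter_mm"].to_numpy(float)
    l = out["longer_mm"].to_numpy(float)
    out["shorter_mm"] = np.minimum(s, l)
    out["longer_mm"] = np.maximum(s, l)
    out["volume_mm3"] = tumour_volume(out["shorter_mm"], out["longer_mm"])
    return out


def growth_summary(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-day mean volume ± SD and animal counts.

    Days at which a group was not measured are simply absent from the
    output.  Input may be a raw caliper table (volumes are derived if
    missing).
    """
    if len(measurements) == 0:
        raise ValueError("no measurements")
    df = measurements
    if "volume_mm3" not in df.columns:
        df = load_caliper_table(df)
    grouped = df.groupby(["group", "day"])["volume_mm3"]
    out = grouped.agg(mean_volume="mean", sd_volume=lambda x: x.std(ddof=1), n="count")
    out = out.reset_index()
    out["sd_volume"] = out["sd_volume"].fillna(0.0)
    return out


def endpoint_summary(measurements: pd.DataFrame, basis: str = "volume") -> pd.Series:
    """Per-group endpoint mean (final-day volume, or terminal weight)."""
    if basis not in ("volume", "weight"):
        raise ValueError("basis must be 'volume' or 'weight'")
    df = measurements
    if "volume_mm3" not in df.columns:
        df = load_caliper_table(df)
    if basis == "volume":
        final_day = df["day"].max()
        endpoint = df.loc[df["day"] == final_day].groupby("group")["volume_mm3"].mean()
    else:
        if "weight_g" not in df.columns:
            raise ValueError("no weight_g column for weight-basis endpoint")
        weights = df.dropna(subset=["weight_g"])
        if len(weights) == 0:
            raise ValueError("no endpoint weights recorded")
        endpoint = weights.groupby("group")["weight_g"].mean()
    return endpoint


def in_vivo_effect(control_endpoint: float, treated_endpoint: float) -> float:
    """Endpoint treatment effect ``E = 1 − treated/control``, clipped to [0, 1]."""
    if control_endpoint <= 0:
        raise ValueError("control endpoint must be positive")
    if treated_endpoint < 0:
        raise ValueError("treated endpoint must be nonnegative")
    return float(min(1.0, max(0.0, 1.0 - treated_endpoint / control_endpoint)))


def treatment_effects(
    measurements: pd.DataFrame,
    control_group: str = "Co",
    basis: str = "volume",
) -> dict[str, float]:
    """Endpoint effect fraction for every treated group vs the control group."""
    endpoints = endpoint_summary(measurements, basis)
    if control_group not in endpoints.index:
        raise ValueError(f"control group {control_group!r} absent")
    control = float(endpoints[control_group])
    return {
        str(group): in_vivo_effect(control, float(value))
        for group, value in endpoints.items()
        if group != control_group
    }


def xeno_viability(
    measurements: pd.DataFrame,
    control_group: str = "Co",
    basis: str = "volume",
    model: str = "Xeno",
):
    """Endpoint ratios expressed in control % for the cross-model comparison.

    Returns a list of :class:`tmshet.drug_response.ViabilityPercent`, one per
    treated group, so the in vivo arms can enter the same sensitivity and
    concordance machinery as the plate assays.
    """
    from .drug_response import ViabilityPercent

    endpoints = endpoint_summary(measurements, basis)
    if control_group not in endpoints.index:
        raise ValueError(f"control group {control_group!r} absent")
    control = float(endpoints[control_group])
    if control <= 0:
        raise ValueError("control endpoint must be positive")
    n_by_group = (
        measurements.groupby("group")["animal_id"].nunique()
        if "animal_id" in measurements.columns
        else None
    )
    out = []
    for group, value in endpoints.items():
        if group == control_group:
            continue
        out.append(
            ViabilityPercent(
                model=model,
                arm=str(group),
                assay=basis,
                mean_percent=100.0 * float(value) / control,
                sd_percent=0.0,
                n=int(n_by_group[group]) if n_by_group is not None else 1,
            )
        )
    return out
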
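"""Drug-response normalization, combination-index synergy and sensitivity calls.

Raw plate readouts (Alamar blue fluorescence, sulforhodamine-B absorbance,
cell counts, or in vivo endpoints) are normalized to the untreated control of
the same model system and assay, expressed in *control %* (100 = control).
Per-model viabilities are averaged across assays, mapped to effect fractions
``E = 1 − viability/100``, and combination arms are assessed with the
combination index

    CI = (Ea + Eb) / Eab

where ``Ea``/``Eb`` are the single-agent effects and ``Eab`` the combination
effect: CI < 1 synergistic, CI = 1 additive (within a tolerance band), CI > 1
no additional effect.  Average viabilities are also binned into four
sensitivity classes (resistant ≥90%, minimal sensitivity 80–90%, sensitive
60–80%, highly sensitive <60%), and agreement of the class patterns across
model systems is scored to rank in vitro models against the xenograft.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_ARM",
    "AssayReadout",
    "ViabilityPercent",
    "CombinationAssessment",
    "SensitivityCall",
    "normalize_to_control",
    "viability_table",
    "average_across_assays",
    "effect_fraction",
    "combination_index",
    "estimate_combination_index",
    "classify_sensitivity",
    "model_concordance",
    "rank_models_by_concordance",
    "sensitivity_matrix",
    "split_combination_arm",
]

CONTROL_ARM = "Co"

#: class boundaries on the control-% scale: resistant >= 90, minimal in
#: [80, 90), sensitive in [60, 80), highly sensitive < 60.
SENSITIVITY_BOUNDS = (60.0, 80.0, 90.0)


@dataclass(frozen=True)
class AssayReadout:
    model: str
    arm: str
    assay: str
    replicate: int
    signal: float

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("signal must be nonnegative")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")


@dataclass(frozen=True)
class ViabilityPercent:
    model: str
    arm: str
    assay: str
    mean_percent: float
    sd_percent: float
    n: int


@dataclass(frozen=True)
class CombinationAssessment:
    ea: float
    eb: float
    eab: float
    ci: float
    interaction: str  # synergistic | additive | no_additional_effect


@dataclass(frozen=True)
class SensitivityCall:
    model: str
    arm: str
    viability_percent: float
    category: str  # resistant | minimal_sensitivity | sensitive | highly_sensitive


def _signals(readouts: Iterable[AssayReadout] | Sequence[float]) -> np.ndarray:
    vals = [r.signal if isinstance(r, AssayReadout) else float(r) for r in readouts]
    return np.asarray(vals, dtype=float)


def normalize_to_control(
    treated: Iterable[AssayReadout] | Sequence[float],
    control: Iterable[AssayReadout] | Sequence[float],
    *,
    model: str = "",
    arm: str = "",
    assay: str = "",
) -> ViabilityPercent:
    """Express treated replicates in control % of the same model/assay.

    ``mean_percent = 100 · mean(treated) / mean(control)``; the SD is that of
    the per-replicate percentages (each treated replicate against the control
    mean).
    """
    treated = list(treated)
    control = list(control)
    t = _signals(treated)
    c = _signals(control)
    if t.size == 0 or c.size == 0:
        raise ValueError("need at least one replicate in both treated and control")
    t_meta = [r for r in treated if isinstance(r, AssayReadout)]
    c_meta = [r for r in control if isinstance(r, AssayReadout)]
    if t_meta and c_meta:
        if {(r.model, r.assay) for r in t_meta} != {(r.model, r.assay) for r in c_meta}:
            raise ValueError("treated and control readouts mix models or assays")
        model = model or t_meta[0].model
        arm = arm or t_meta[0].arm
        assay = assay or t_meta[0].assay
    c_mean = c.mean()
    if c_mean <= 0:
        raise ValueError("control mean must be positive")
    percents = 100.0 * t / c_mean
    sd = float(percents.std(ddof=1)) if percents.size > 1 else 0.0
    return ViabilityPercent(
        model=model,
        arm=arm,
        assay=assay,
        mean_percent=float(percents.mean()),
        sd_percent=sd,
        n=int(percents.size),
    )


def viability_table(
    assays: pd.DataFrame, control_arm: str = CONTROL_ARM
) -> list[ViabilityPercent]:
    """Normalize every (model, assay, arm) cell of a raw readout table.

    ``assays`` follows the CSV schema ``model, arm, assay, replicate, signal``.
    The control arm itself is reported too (its mean is 100 by construction).
    """
    needed = {"model", "arm", "assay", "signal"}
    missing = needed - set(assays.columns)
    if missing:
        raise ValueError(f"assay table is missing columns: {sorted(missing)}")
    out: list[ViabilityPercent] = []
    for (model, assay), cell in assays.groupby(["model", "assay"], sort=False):
        control = cell.loc[cell["arm"] == control_arm, "signal"].to_numpy()
        if control.size == 0:
            raise ValueError(f"no {control_arm!r} arm for model {model!r}, assay {assay!r}")
        for arm, arm_rows in cell.groupby("arm", sort=False):
            out.append(
                normalize_to_control(
                    arm_rows["signal"].to_numpy(),
                    control,
                    model=str(model),
                    arm=str(arm),
                    assay=str(assay),
                )
            )
    return out


def average_across_assays(results: Sequence[ViabilityPercent]) -> ViabilityPercent:
    """Unweighted mean of per-assay viabilities for one model/arm."""
    if len(results) == 0:
        raise ValueError("need at least one viability result")
    keys = {(r.model, r.arm) for r in results}
    if len(keys) > 1:
        raise ValueError(f"results mix model/arm cells: {sorted(keys)}")
    model, arm = next(iter(keys))
    means = np.array([r.mean_percent for r in results])
    return ViabilityPercent(
        model=model,
        arm=arm,
        assay="average",
        mean_percent=float(means.mean()),
        sd_percent=float(means.std(ddof=1)) if means.size > 1 else 0.0,
        n=int(sum(r.n for r in results)),
    )


def effect_fraction(v: ViabilityPercent | float) -> float:
    """Fractional inhibition ``E = 1 − viability/100``, clipped to [0, 1].

    Viabilities above control (stimulation) clip to zero effect rather than
    propagating negative effects into the combination index.
    """
    percent = v.mean_percent if isinstance(v, ViabilityPercent) else float(v)
    if percent < 0:
        raise ValueError("viability percent must be >= 0")
    return float(min(1.0, max(0.0, 1.0 - percent / 100.0)))


def combination_index(
    ea: float, eb: float, eab: float, additivity_tol: float = 0.05
) -> CombinationAssessment:
    """Combination index ``(Ea + Eb)/Eab`` with its interaction class.

    Exact additivity (CI = 1) has measure zero on noisy data, so a tolerance
    band ``|CI − 1| <= additivity_tol`` is called additive; below the band is
    synergistic, above it no additional effect.
    """
    for name, e in (("ea", ea), ("eb", eb), ("eab", eab)):
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {e}")
    if eab == 0:
        raise ValueError("combination effect is zero: combination index undefined")
    if additivity_tol < 0:
        raise ValueError("additivity_tol must be >= 0")
    ci = (ea + eb) / eab
    if ci < 1.0 - additivity_tol:
        interaction = "synergistic"
    elif ci <= 1.0 + additivity_tol:
        interaction = "additive"
    else:
        interaction = "no_additional_effect"
    return CombinationAssessment(ea=ea, eb=eb, eab=eab, ci=ci, interaction=interaction)


def estimate_combination_index(
    mono_a: ViabilityPercent,
    mono_b: ViabilityPercent,
    combo: ViabilityPercent,
    additivity_tol: float = 0.05,
) -> tuple[CombinationAssessment, float]:
    """Combination index from measured viabilities, with a delta-method SE.

    Effects are ``E = 1 − v/100``; the standard error of the index is
    propagated from the standard errors of the three mean viabilities
    (independent arms assumed).
    """
    ea, eb, eab = (effect_fraction(v) for v in (mono_a, mono_b, combo))
    assessment = combination_index(ea, eb, eab, additivity_tol)
    ses = [
        (v.sd_percent / 100.0) / math.sqrt(max(v.n, 1))
        for v in (mono_a, mono_b, combo)
    ]
    se_num = math.hypot(ses[0], ses[1])
    ci = assessment.ci
    se_ci = abs(ci) * math.sqrt(
        (se_num / max(ea + eb, 1e-12)) ** 2 + (ses[2] / max(eab, 1e-12)) ** 2
    )
    return assessment, se_ci


def classify_sensitivity(
    v: ViabilityPercent | float,
    *,
    model: str = "",
    arm: str = "",
    bounds: tuple[float, float, float] = SENSITIVITY_BOUNDS,
) -> SensitivityCall:
    """Bin an average viability into the four-class sensitivity scheme."""
    percent = v.mean_percent if isinstance(v, ViabilityPercent) else float(v)
    if percent < 0:
        raise ValueError("viability percent must be >= 0")
    lo, mid, hi = bounds
    if not lo < mid < hi:
        raise ValueError("sensitivity bounds must be increasing")
    if percent >= hi:
        category = "resistant"
    elif percent >= mid:
        category = "minimal_sensitivity"
    elif percent >= lo:
        category = "sensitive"
    else:
        category = "highly_sensitive"
    if isinstance(v, ViabilityPercent):
        model = model or v.model
        arm = arm or v.arm
    return SensitivityCall(model=model, arm=arm, viability_percent=percent, category=category)


def model_concordance(
    calls_a: Mapping[str, SensitivityCall],
    calls_b: Mapping[str, SensitivityCall],
) -> tuple[float, pd.DataFrame]:
    """Fraction of arms on which two models receive the same sensitivity class.

    Returns the agreement fraction and a per-arm match table (classes of both
    models, match flag, absolute viability difference).
    """
    if set(calls_a) != set(calls_b):
        raise ValueError(
            f"arm sets differ: {sorted(calls_a)} vs {sorted(calls_b)}"
        )
    if not calls_a:
        raise ValueError("no arms to compare")
    rows = []
    for arm in calls_a:
        a, b = calls_a[arm], calls_b[arm]
        rows.append(
            {
                "arm": arm,
                "category_a": a.category,
                "category_b": b.category,
                "match": a.category == b.category,
                "abs_viability_diff": abs(a.viability_percent - b.viability_percent),
            }
        )
    table = pd.DataFrame(rows)
    return float(table["match"].mean()), table


def rank_models_by_concordance(
    calls_by_model: Mapping[str, Mapping[str, SensitivityCall]],
    reference: str,
) -> pd.DataFrame:
    """Rank candidate models by class agreement with a reference model.

    Ties in agreement are broken by the mean absolute viability difference
    (closer wins).  Returns a DataFrame sorted best-first.
    """
    if reference not in calls_by_model:
        raise ValueError(f"reference model {reference!r} missing")
    ref = calls_by_model[reference]
    rows = []
    for model, calls in calls_by_model.items():
        if model == reference:
            continue
        agreement, table = model_concordance(calls, ref)
        rows.append(
            {
                "model": model,
                "agreement": agreement,
                "mean_abs_viability_diff": float(table["abs_viability_diff"].mean()),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["agreement", "mean_abs_viability_diff"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


def split_combination_arm(arm: str) -> tuple[str, str] | None:
    """Return the component arms of a combination label like ``R+doxy``."""
    if "+" not in arm:
        return None
    a, b = arm.split("+", 1)
    return a.strip(), b.strip()


def sensitivity_matrix(
    assays: pd.DataFrame,
    control_arm: str = CONTROL_ARM,
    additivity_tol: float = 0.05,
) -> pd.DataFrame:
    """Full model × arm sensitivity grid from a raw readout table.

    Each treated arm is normalized per assay, averaged across the model's
    assays and classified; combination arms additionally carry the
    combination index computed from the averaged mono- and combination
    viabilities, and a synergy flag.
    """
    per_assay = viability_table(assays, control_arm)
    by_cell: dict[tuple[str, str], list[ViabilityPercent]] = {}
    for v in per_assay:
        by_cell.setdefault((v.model, v.arm), []).append(v)
    averages = {cell: average_across_assays(vs) for cell, vs in by_cell.items()}

    rows = []
    for (model, arm), avg in averages.items():
        row: dict[str, object] = {
            "model": model,
            "arm": arm,
            "viability_percent": avg.mean_percent,
            "sd_percent": avg.sd_percent,
            "category": classify_sensitivity(avg).category,
            "ci": np.nan,
            "interaction": "",
            "synergistic": False,
        }
        parts = split_combination_arm(arm)
        if parts is not None:
            mono_a, mono_b = (averages.get((model, p)) for p in parts)
            if mono_a is not None and mono_b is not None:
                assessment = combination_index(
                    effect_fraction(mono_a),
                    effect_fraction(mono_b),
                    effect_fraction(avg),
                    additivity_tol,
                )
                row["ci"] = assessment.ci
                row["interaction"] = assessment.interaction
                row["synergistic"] = assessment.interaction == "synergistic"
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["model", "arm"]).reset_index(drop=True)
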
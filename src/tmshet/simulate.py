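"""Synthetic inputs with the statistical structure the scoring stages assume.

Three generators emulate the study's three data streams:

* **Cohorts** of immunostained samples: each sample's latent intensity
  distribution is Dirichlet — a spread, symmetric draw for heterogeneous
  samples, a dominant-bin draw for homogeneous ones — with the per-marker
  probability of heterogeneity set by the marker's prevalence.  Two observers
  then each grade ``n_cells`` cells by multinomial sampling from the latent
  distribution.
* **Treatment plates**: replicate signals per (model, arm, assay) with
  multiplicative Gaussian noise around the configured true viability; the
  true viability of a combination arm is derived from the monotherapy
  effects and a configurable true combination index.
* **Xenograft studies**: per-animal exponential tumour growth with
  treatment-scaled endpoints, measured thrice weekly over 21 days via two
  jittered caliper diameters.

All generators are deterministic given their seed and emit the same CSV
schemas the scoring modules ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets

__all__ = [
    "CohortSimConfig",
    "PlateSimConfig",
    "XenoSimConfig",
    "generate_cohort",
    "generate_assay_plate",
    "generate_xenograft_study",
    "DEFAULT_TRUE_VIABILITY",
    "DEFAULT_TRUE_CI",
]

SUBTYPES = datasets.SUBTYPES

# Latent-profile guard bands around the 0.10 per-sample call threshold: a
# heterogeneous sample must carry a second population of at least 15% of
# cells, a homogeneous one at most 5% strays, so the latent label survives
# cell-sampling noise.
HET_MIN_MINOR = 0.15
HOMOG_MAX_MINOR = 0.05


@dataclass
class CohortSimConfig:
    """Configuration of the synthetic immunostaining cohort.

    ``markers`` maps marker name to heterogeneity prevalence θ in [0, 1];
    the default panel carries the 14 reference markers at their pooled
    empirical prevalences.  ``concentration_het`` is the symmetric Dirichlet
    concentration of heterogeneous latent profiles (1.0 gives median SDI
    ≈ 1.1); ``concentration_homog`` is the dominant-bin concentration of
    homogeneous profiles (15.0 gives SDI ≈ 0.3).
    """

    markers: Mapping[str, float] = field(default_factory=datasets.marker_prevalence)
    n_per_subtype: int | Mapping[str, int] = 10
    subtypes: Sequence[str] = SUBTYPES
    concentration_homog: float = 15.0
    concentration_het: float = 1.0
    n_cells_per_sample: int = 200
    n_observers: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for marker, theta in self.markers.items():
            if not 0.0 <= theta <= 1.0:
                raise ValueError(f"prevalence for {marker!r} must lie in [0, 1]")
        if self.concentration_homog <= 0 or self.concentration_het <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.n_cells_per_sample < 1:
            raise ValueError("n_cells_per_sample must be >= 1")

    def n_for(self, subtype: str) -> int:
        if isinstance(self.n_per_subtype, Mapping):
            return int(self.n_per_subtype[subtype])
        return int(self.n_per_subtype)


def _draw_het_profile(rng: np.random.Generator, concentration: float) -> np.ndarray:
    # spread Dirichlet conditioned on a real second population
    while True:
        p = rng.dirichlet(np.full(4, concentration))
        if np.count_nonzero(p >= HET_MIN_MINOR) >= 2:
            return p


def _draw_homog_profile(rng: np.random.Generator, concentration: float) -> np.ndarray:
    # dominant-bin Dirichlet conditioned on only stray off-bin cells
    while True:
        alpha = np.full(4, 1.0)
        alpha[rng.integers(4)] = concentration
        p = rng.dirichlet(alpha)
        if np.sort(p)[-2] <= HOMOG_MAX_MINOR:
            return p


def generate_cohort(
    config: CohortSimConfig, return_truth: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort table (schema of ``cohort.csv``).

    With ``return_truth`` the latent per-sample ground truth (heterogeneity
    label and latent fractions) is returned alongside.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    truth_rows = []
    for marker, theta in config.markers.items():
        for subtype in config.subtypes:
            for i in range(config.n_for(subtype)):
                sample_id = f"{subtype}-{i + 1:02d}"
                heterogeneous = bool(rng.random() < theta)
                if heterogeneous:
                    latent = _draw_het_profile(rng, config.concentration_het)
                else:
                    latent = _draw_homog_profile(rng, config.concentration_homog)
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "marker": marker,
                        "subtype": subtype,
                        "heterogeneous_true": heterogeneous,
                        **{f"latent_p{j}": latent[j] for j in range(4)},
                    }
                )
                for obs in range(1, config.n_observers + 1):
                    counts = rng.multinomial(config.n_cells_per_sample, latent)
                    fracs = counts / counts.sum()
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "marker": marker,
                            "subtype": subtype,
                            "observer": f"obs{obs}",
                            "p0": fracs[0],
                            "p1": fracs[1],
                            "p2": fracs[2],
                            "p3": fracs[3],
                            "n_cells": config.n_cells_per_sample,
                        }
                    )
    cohort = pd.DataFrame(rows)
    if return_truth:
        return cohort, pd.DataFrame(truth_rows)
    return cohort


# ---------------------------------------------------------------------------
# treatment plates
# ---------------------------------------------------------------------------

#: default true viabilities (control %) of the monotherapy arms, chosen to
#: mirror the qualitative cross-model sensitivity pattern: monolayers respond
#: to everything, spheroids to rapamycin and doxorubicin, bioprinted scaffolds
#: show minimal rapamycin sensitivity and doxycycline/doxorubicin resistance,
#: and xenografts resist all monotherapies.
DEFAULT_TRUE_VIABILITY: dict[str, dict[str, float]] = {
    "2D": {"R": 55.0, "doxy": 50.0, "doxo": 45.0},
    "3D-spheroid-ULA": {"R": 70.0, "doxy": 92.0, "doxo": 65.0},
    "3D-TMS": {"R": 85.0, "doxy": 93.0, "doxo": 95.0},
    "Xeno": {"R": 90.0, "doxy": 92.0, "doxo": 94.0},
}

#: default true combination indices; strong synergy in the scaffold and
#: xenograft systems pulls their combination arms below 60% viability even
#: though the monotherapy effects there are small.
DEFAULT_TRUE_CI: dict[str, dict[str, float]] = {
    "2D": {"R+doxy": 1.0, "R+doxo": 1.0},
    "3D-spheroid-ULA": {"R+doxy": 0.9, "R+doxo": 0.9},
    "3D-TMS": {"R+doxy": 0.4, "R+doxo": 0.4},
    "Xeno": {"R+doxy": 0.3, "R+doxo": 0.3},
}

DEFAULT_ASSAYS: dict[str, tuple[str, ...]] = {
    "2D": ("AB", "SRB", "cell_count"),
    "3D-spheroid-ULA": ("AB", "cell_count"),
    "3D-TMS": ("AB", "mSRB"),
    "Xeno": ("volume",),
}

#: arbitrary per-assay unit scales (fluorescence, absorbance, counts, ...)
#: so normalization to control % is actually exercised.
DEFAULT_ASSAY_SCALE: dict[str, float] = {
    "AB": 120.0,
    "SRB": 1.6,
    "mSRB": 1.6,
    "cell_count": 250.0,
    "volume": 4.0,
}


@dataclass
class PlateSimConfig:
    """Configuration of the synthetic 72-h treatment plates.

    ``viability`` holds the true monotherapy viabilities per model (control
    %); ``ci`` the true combination index of each combination arm, from which
    the combination viability follows as ``Eab = (Ea + Eb)/ci`` truncated to
    [0, 1].  Replicate signals carry multiplicative Gaussian noise with
    coefficient of variation ``cv``, truncated at zero.
    """

    viability: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_TRUE_VIABILITY.items()}
    )
    ci: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_TRUE_CI.items()}
    )
    assays: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {m: tuple(v) for m, v in DEFAULT_ASSAYS.items()}
    )
    assay_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ASSAY_SCALE)
    )
    cv: float = 0.10
    replicates: int = 6
    control_arm: str = "Co"
    seed: int = 0

    def __post_init__(self) -> None:
        for model, arms in self.viability.items():
            for arm, v in arms.items():
                if v < 0:
                    raise ValueError(f"true viability must be >= 0 ({model}/{arm})")
        for model, arms in self.ci.items():
            for arm, ci in arms.items():
                if ci <= 0:
                    raise ValueError(f"true combination index must be > 0 ({model}/{arm})")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def true_viabilities(self, model: str) -> dict[str, float]:
        """All true arm viabilities of one model, combinations included."""
        monos = dict(self.viability[model])
        out = {self.control_arm: 100.0, **monos}
        for arm, ci_true in self.ci.get(model, {}).items():
            parts = arm.split("+")
            effects = [1.0 - monos[p.strip()] / 100.0 for p in parts]
            eab = min(1.0, max(0.0, sum(effects) / ci_true))
            out[arm] = 100.0 * (1.0 - eab)
        return out


def generate_assay_plate(config: PlateSimConfig) -> pd.DataFrame:
    """Simulate a raw readout table (schema of ``assays.csv``)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for model in config.viability:
        arm_viability = config.true_viabilities(model)
        for assay in config.assays.get(model, ("AB",)):
            scale = float(config.assay_scale.get(assay, 1.0))
            for arm, v_true in arm_viability.items():
                noise = rng.normal(0.0, config.cv, size=config.replicates)
                signals = np.maximum(0.0, scale * v_true * (1.0 + noise))
                for rep, signal in enumerate(signals, start=1):
                    rows.append(
                        {
                            "model": model,
                            "arm": arm,
                            "assay": assay,
                            "replicate": rep,
                            "signal": signal,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# xenograft studies
# ---------------------------------------------------------------------------

#: endpoint volume multipliers matching the Xeno plate defaults
#: (viability % / 100 of the corresponding arm).
DEFAULT_XENO_MULTIPLIERS: dict[str, float] = {
    "Co": 1.0,
    "R": 0.90,
    "doxy": 0.92,
    "doxo": 0.94,
    "R+doxy": 0.40,
    "R+doxo": 0.467,
}

THRICE_WEEKLY_21D = (0, 2, 4, 7, 9, 11, 14, 16, 18, 21)


@dataclass
class XenoSimConfig:
    """Configuration of the synthetic 21-day xenograft study.

    Control tumours grow exponentially from ``initial_volume_mm3`` at
    ``growth_rate`` per day; each treated group's rate is shifted so that its
    day-21 endpoint equals the control endpoint times the group's multiplier.
    Caliper diameters are back-computed from the spherical volume and
    jittered with Gaussian noise of SD ``diameter_noise_mm``.
    """

    groups: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_XENO_MULTIPLIERS)
    )
    growth_rate: float = math.log(6.0) / 21.0  # per day; control ×6 over 21 d
    initial_volume_mm3: float = 100.0
    diameter_noise_mm: float = 0.3
    days: Sequence[int] = THRICE_WEEKLY_21D
    n_animals: int = 8
    tissue_density_g_per_mm3: float = 1.05e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_rate <= 0 or self.initial_volume_mm3 <= 0:
            raise ValueError("growth rate and initial volume must be positive")
        for group, m in self.groups.items():
            if m <= 0:
                raise ValueError(f"multiplier for {group!r} must be > 0")
        if self.diameter_noise_mm < 0:
            raise ValueError("diameter noise must be >= 0")
        if self.n_animals < 1:
            raise ValueError("need at least one animal per group")


def generate_xenograft_study(config: XenoSimConfig) -> pd.DataFrame:
    """Simulate a caliper table (schema of ``calipers.csv``)."""
    rng = np.random.default_rng(config.seed)
    total_days = max(config.days)
    rows = []
    for group, multiplier in config.groups.items():
        rate = config.growth_rate + math.log(multiplier) / total_days
        for animal in range(1, config.n_animals + 1):
            animal_id = f"{group}-{animal:02d}"
            for day in config.days:
                volume = config.initial_volume_mm3 * math.exp(rate * day)
                diameter = (6.0 * volume / math.pi) ** (1.0 / 3.0)
                d1, d2 = diameter + rng.normal(0.0, config.diameter_noise_mm, size=2)
                d1, d2 = max(d1, 0.1), max(d2, 0.1)
                weight = (
                    volume * config.tissue_density_g_per_mm3 if day == total_days else np.nan
                )
                rows.append(
                    {
                        "animal_id": animal_id,
                        "group": group,
                        "day": day,
                        "shorter_mm": min(d1, d2),
                        "longer_mm": max(d1, d2),
                        "weight_g": weight,
                    }
                )
    return pd.DataFrame(rows)
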
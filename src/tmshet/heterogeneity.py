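"""Immunostaining heterogeneity scoring.

Pathologists grade the nuclear/cytoplasmic staining of each evaluated cell
into four ordinal intensity bins (0, +, ++, +++).  A sample is then described
by the fraction vector ``p = (p0, p1, p2, p3)`` of cells in each bin, from
which two standard summaries are computed:

* the **H-score** ``100 · Σ i·p_i`` (range 0–300), the workhorse
  semi-quantitative IHC score, and
* the **Shannon Diversity Index** ``SDI = −Σ p_i ln p_i`` (range 0–ln 4),
  which quantifies intra-tumoural staining heterogeneity: 0 for a perfectly
  homogeneous sample and ln 4 when the four intensities are equally frequent.

A sample is called *heterogeneous* when at least two intensity bins each hold
a non-trivial share of cells (default ≥10%).  A marker is called
heterogeneous at the cohort level when more than 40% of the evaluable samples
(pooled over subtypes) are heterogeneous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .datasets import reference_heterogeneity_counts

__all__ = [
    "N_BINS",
    "MAX_SDI",
    "IntensityProfile",
    "SampleScore",
    "CohortHeterogeneity",
    "intensity_fractions",
    "h_score",
    "shannon_diversity",
    "consensus_profile",
    "call_sample_heterogeneity",
    "score_sample",
    "summarize_marker",
    "sdi_model_table",
    "score_cohort",
    "heterogeneity_table",
    "audit_reference_table",
    "round_half_away",
]

N_BINS = 4
MAX_SDI = math.log(N_BINS)
_SUM_TOL = 1e-9


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (68.5 -> 69)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class IntensityProfile:
    """Per-sample distribution of cells over the four staining intensities."""

    sample_id: str
    marker: str
    fractions: np.ndarray
    subtype: str = ""
    observer: str = ""
    n_cells: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.fractions, dtype=float)
        if p.shape != (N_BINS,):
            raise ValueError(f"fractions must have length {N_BINS}, got shape {p.shape}")
        if np.any(p < 0) or np.any(p > 1 + _SUM_TOL):
            raise ValueError(f"fractions must lie in [0, 1]: {p}")
        total = p.sum()
        if total <= 0:
            raise ValueError("fractions sum to zero: empty sample")
        if abs(total - 1.0) > _SUM_TOL:
            p = p / total
        p = np.clip(p, 0.0, 1.0)
        object.__setattr__(self, "fractions", p)
        if self.n_cells is not None and self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass(frozen=True)
class SampleScore:
    sample_id: str
    marker: str
    h_score: float
    sdi: float
    heterogeneous: bool
    group: str = ""  # subtype or model label; used for cross-model tables


@dataclass(frozen=True)
class CohortHeterogeneity:
    """Per-marker cohort summary: counts by subtype, pooled percent, >40% flag."""

    marker: str
    per_subtype: Mapping[str, tuple[int, int]]
    pooled_percent: int
    is_heterogeneous_marker: bool
    flag_percent: float = 40.0

    @property
    def pooled_counts(self) -> tuple[int, int]:
        k = sum(v[0] for v in self.per_subtype.values())
        n = sum(v[1] for v in self.per_subtype.values())
        return k, n


def intensity_fractions(counts: Sequence[float]) -> np.ndarray:
    """Convert per-bin cell counts to fractions summing to one."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (N_BINS,):
        raise ValueError(f"counts must have length {N_BINS}")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero counts: empty sample")
    return c / total


def _fractions(profile: IntensityProfile | Sequence[float]) -> np.ndarray:
    if isinstance(profile, IntensityProfile):
        return profile.fractions
    return IntensityProfile("", "", np.asarray(profile, float)).fractions


def h_score(profile: IntensityProfile | Sequence[float]) -> float:
    """H-score ``100 · (0·p0 + 1·p1 + 2·p2 + 3·p3)`` on the 0–300 scale."""
    p = _fractions(profile)
    return float(100.0 * np.dot(np.arange(N_BINS), p))


def shannon_diversity(profile: IntensityProfile | Sequence[float]) -> float:
    """Shannon Diversity Index ``−Σ p_i ln p_i`` (natural log, 0·ln0 = 0)."""
    p = _fractions(profile)
    return float(_scipy_entropy(p))


def consensus_profile(profiles: Sequence[IntensityProfile]) -> IntensityProfile:
    """Combine independent observers' readings of one sample/marker.

    The consensus is the element-wise mean of the observers' fraction
    vectors (renormalized); a single profile is returned unchanged apart
    from the observer label.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    first = profiles[0]
    for prof in profiles[1:]:
        if (prof.sample_id, prof.marker) != (first.sample_id, first.marker):
            raise ValueError(
                "profiles disagree on sample/marker: "
                f"{(prof.sample_id, prof.marker)} vs {(first.sample_id, first.marker)}"
            )
    mean = np.mean([prof.fractions for prof in profiles], axis=0)
    n_cells = None
    counted = [prof.n_cells for prof in profiles if prof.n_cells is not None]
    if counted:
        n_cells = int(sum(counted))
    return replace(first, fractions=mean, observer="consensus", n_cells=n_cells)


def call_sample_heterogeneity(
    profile: IntensityProfile | Sequence[float], min_minor_fraction: float = 0.10
) -> bool:
    """Per-sample heterogeneity call.

    True iff at least two intensity bins each hold a fraction of at least
    ``min_minor_fraction``, i.e. a second staining population is present
    beyond stray cells.  The threshold must lie in (0, 0.5].
    """
    if not 0.0 < min_minor_fraction <= 0.5:
        raise ValueError("min_minor_fraction must lie in (0, 0.5]")
    p = _fractions(profile)
    return int(np.count_nonzero(p >= min_minor_fraction)) >= 2


def score_sample(
    profile: IntensityProfile, min_minor_fraction: float = 0.10
) -> SampleScore:
    return SampleScore(
        sample_id=profile.sample_id,
        marker=profile.marker,
        h_score=h_score(profile),
        sdi=shannon_diversity(profile),
        heterogeneous=call_sample_heterogeneity(profile, min_minor_fraction),
        group=profile.subtype,
    )


def summarize_marker(
    calls: Mapping[str, Sequence[bool]],
    marker: str,
    flag_percent: float = 40.0,
) -> CohortHeterogeneity:
    """Aggregate per-sample heterogeneity calls into a cohort-level call.

    The pooled percentage is computed from pooled counts (Σhet/Σeval over
    subtypes with at least one evaluated sample, ×100, rounded half away
    from zero); the marker is flagged when it strictly exceeds
    ``flag_percent``.
    """
    per_subtype = {
        subtype: (int(sum(bool(c) for c in subtype_calls)), len(subtype_calls))
        for subtype, subtype_calls in calls.items()
        if len(subtype_calls) > 0
    }
    if not per_subtype:
        raise ValueError("no subtype has any heterogeneity calls")
    k = sum(v[0] for v in per_subtype.values())
    n = sum(v[1] for v in per_subtype.values())
    pooled = round_half_away(100.0 * k / n)
    return CohortHeterogeneity(
        marker=marker,
        per_subtype=per_subtype,
        pooled_percent=pooled,
        is_heterogeneous_marker=pooled > flag_percent,
        flag_percent=flag_percent,
    )


def sdi_model_table(
    scores: Iterable[SampleScore],
    compare: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Mean SDI per (marker, group) cell, one row per marker.

    ``group`` is whatever label the scores carry (subtype or model system,
    e.g. ``Xeno`` vs ``3D-TMS``).  Cells with no scores are left absent
    (NaN), never imputed as zero.  When ``compare`` names two groups, a
    column ``abs_diff`` with the per-marker absolute difference of their
    means is appended.
    """
    records = [
        {"marker": s.marker, "group": s.group, "sdi": s.sdi} for s in scores
    ]
    if not records:
        raise ValueError("no scores provided")
    df = pd.DataFrame(records)
    table = df.pivot_table(index="marker", columns="group", values="sdi", aggfunc="mean")
    table.columns.name = None
    if compare is not None:
        a, b = compare
        for g in (a, b):
            if g not in table.columns:
                raise ValueError(f"group {g!r} absent from scores")
        table["abs_diff"] = (table[a] - table[b]).abs()
    return table


# ---------------------------------------------------------------------------
# cohort-table plumbing (CSV schema: sample_id, marker, subtype, observer,
# p0..p3, n_cells)
# ---------------------------------------------------------------------------

def profiles_from_table(df: pd.DataFrame) -> list[IntensityProfile]:
    needed = {"sample_id", "marker", "p0", "p1", "p2", "p3"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    profiles = []
    for row in df.itertuples(index=False):
        n_cells = getattr(row, "n_cells", None)
        profiles.append(
            IntensityProfile(
                sample_id=str(row.sample_id),
                marker=str(row.marker),
                fractions=np.array([row.p0, row.p1, row.p2, row.p3], float),
                subtype=str(getattr(row, "subtype", "")),
                observer=str(getattr(row, "observer", "")),
                n_cells=None if n_cells is None or pd.isna(n_cells) else int(n_cells),
            )
        )
    return profiles


def score_cohort(
    cohort: pd.DataFrame,
    min_minor_fraction: float = 0.10,
    flag_percent: float = 40.0,
) -> tuple[pd.DataFrame, list[CohortHeterogeneity]]:
    """Score a whole cohort table.

    Observer replicates of each (marker, sample) are first merged into a
    consensus profile; each consensus is scored (H-score, SDI, per-sample
    call) and the calls are aggregated per marker across subtypes.

    Returns the per-sample score table and the per-marker cohort summaries.
    """
    profiles = profiles_from_table(cohort)
    by_key: dict[tuple[str, str], list[IntensityProfile]] = {}
    for prof in profiles:
        by_key.setdefault((prof.marker, prof.sample_id), []).append(prof)

    score_rows = []
    calls: dict[str, dict[str, list[bool]]] = {}
    for (marker, sample_id), group in by_key.items():
        consensus = consensus_profile(group)
        score = score_sample(consensus, min_minor_fraction)
        score_rows.append(
            {
                "sample_id": sample_id,
                "marker": marker,
                "subtype": consensus.subtype,
                "h_score": score.h_score,
                "sdi": score.sdi,
                "heterogeneous": score.heterogeneous,
            }
        )
        calls.setdefault(marker, {}).setdefault(consensus.subtype, []).append(
            score.heterogeneous
        )

    summaries = [
        summarize_marker(calls[marker], marker, flag_percent) for marker in calls
    ]
    scores = pd.DataFrame(score_rows).sort_values(["marker", "sample_id"]).reset_index(drop=True)
    return scores, summaries


def heterogeneity_table(summaries: Sequence[CohortHeterogeneity]) -> pd.DataFrame:
    """Lay out cohort summaries as one row per marker with ``k/n`` strings."""
    subtypes: list[str] = []
    for s in summaries:
        for subtype in s.per_subtype:
            if subtype not in subtypes:
                subtypes.append(subtype)
    rows = []
    for s in summaries:
        row: dict[str, object] = {"marker": s.marker}
        for subtype in subtypes:
            if subtype in s.per_subtype:
                k, n = s.per_subtype[subtype]
                row[subtype] = f"{k}/{n}"
            else:
                row[subtype] = ""
        row["pooled_percent"] = s.pooled_percent
        row["heterogeneous_marker"] = s.is_heterogeneous_marker
        rows.append(row)
    return pd.DataFrame(rows)


def audit_reference_table(flag_percent: float = 40.0) -> pd.DataFrame:
    """Recompute the bundled reference panel's pooled percentages.

    For every marker the pooled percent is recomputed from the per-subtype
    heterogeneous/evaluated counts and compared with the percentage printed
    in the source table.  Markers whose printed value is not reproducible
    from their own counts are flagged (``consistent == False``); the printed
    value is reported but never substituted.
    """
    counts = reference_heterogeneity_counts()
    rows = []
    for marker, sub in counts.groupby("marker", sort=False):
        k = int(sub["n_heterogeneous"].sum())
        n = int(sub["n_evaluated"].sum())
        recomputed = round_half_away(100.0 * k / n)
        printed = int(sub["printed_percent"].iloc[0])
        rows.append(
            {
                "marker": marker,
                "pooled_heterogeneous": k,
                "pooled_evaluated": n,
                "recomputed_percent": recomputed,
                "printed_percent": printed,
                "consistent": recomputed == printed,
                "heterogeneous_marker": recomputed > flag_percent,
            }
        )
    return pd.DataFrame(rows)
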
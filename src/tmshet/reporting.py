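"""Pipeline orchestration and report tables.

``run_pipeline`` ties the stages together: it scores whichever inputs a
:class:`RunConfig` provides (cohort staining table, raw assay readouts,
caliper measurements), writes the report CSVs — heterogeneity table, SDI
comparison, sensitivity matrix, growth curves — plus a JSON run manifest
carrying the config hash and seed.  Every CSV starts with a comment line
declaring the config hash that produced it, so outputs are traceable;
generation is fully deterministic given inputs and config.  On failure,
partially written outputs are removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import __version__
from .drug_response import sensitivity_matrix
from .heterogeneity import heterogeneity_table, score_cohort, sdi_model_table, SampleScore
from .xenograft import growth_summary, load_caliper_table

logger = logging.getLogger("tmshet")

__all__ = ["RunConfig", "run_pipeline", "significance_annotations", "write_report_csv"]


@dataclass
class RunConfig:
    cohort_csv: str | None = None
    assays_csv: str | None = None
    calipers_csv: str | None = None
    out_dir: str = "report"
    min_minor_fraction: float = 0.10
    cohort_flag_percent: float = 40.0
    additivity_tol: float = 0.05
    sensitivity_bounds: tuple[float, float, float] = (60.0, 80.0, 90.0)
    control_arm: str = "Co"
    control_group: str = "Co"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.min_minor_fraction <= 0.5:
            raise ValueError("min_minor_fraction must lie in (0, 0.5]")
        if not 0.0 <= self.cohort_flag_percent <= 100.0:
            raise ValueError("cohort_flag_percent must lie in [0, 100]")
        if self.additivity_tol < 0:
            raise ValueError("additivity_tol must be >= 0")
        lo, mid, hi = self.sensitivity_bounds
        if not 0 < lo < mid < hi:
            raise ValueError("sensitivity bounds must be increasing and positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sensitivity_bounds"] = list(self.sensitivity_bounds)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "sensitivity_bounds" in d:
            d["sensitivity_bounds"] = tuple(d["sensitivity_bounds"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (thresholds, bounds, seed).

        Filesystem locations are excluded so that identical analyses of
        identical inputs hash identically wherever they run; input file
        *content* hashes are recorded separately in the run manifest.
        """
        d = self.to_dict()
        for key in ("cohort_csv", "assays_csv", "calipers_csv", "out_dir", "log_level"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_report_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    """Write a CSV with a leading ``# config_hash=`` comment line."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def significance_annotations(
    groups: Mapping[str, Sequence[float]],
    control: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-arm significance markers from replicate viability sets.

    A one-way ANOVA across all groups is followed by Tukey's HSD; each
    non-control arm is annotated with its Tukey-adjusted p-value against the
    control arm (or, without a designated control, the smallest adjusted
    p-value against any other arm).  Degenerate inputs — fewer than two
    groups, or no variance anywhere with equal means — are flagged as
    untestable rather than raising.
    """
    names = list(groups)
    if len(names) < 2 or any(len(groups[g]) < 2 for g in names):
        return pd.DataFrame(
            {"arm": names, "p_value": np.nan, "significant": False, "test": "untestable"}
        )
    values = np.concatenate([np.asarray(groups[g], float) for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])

    pooled_var = np.var(values - np.concatenate(
        [np.full(len(groups[g]), np.mean(groups[g])) for g in names]
    ))
    means = {g: float(np.mean(groups[g])) for g in names}
    if pooled_var == 0.0:
        # zero within-group variance: any mean difference is trivially real,
        # equal means are untestable
        rows = []
        ref = control if control is not None else names[0]
        for g in names:
            if g == (control if control is not None else None):
                continue
            differs = any(means[g] != means[o] for o in names if o != g)
            rows.append(
                {
                    "arm": g,
                    "p_value": 0.0 if differs else np.nan,
                    "significant": differs,
                    "test": "degenerate (zero variance)",
                }
            )
        return pd.DataFrame(rows)

    f_stat, anova_p = stats.f_oneway(*(np.asarray(groups[g], float) for g in names))
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    summary = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    rows = []
    for g in names:
        if control is not None and g == control:
            continue
        if control is not None:
            mask = ((summary["group1"] == g) & (summary["group2"] == control)) | (
                (summary["group1"] == control) & (summary["group2"] == g)
            )
        else:
            mask = (summary["group1"] == g) | (summary["group2"] == g)
        p_adj = float(summary.loc[mask, "p-adj"].min())
        rows.append(
            {
                "arm": g,
                "p_value": p_adj,
                "significant": p_adj <= alpha,
                "test": "one-way ANOVA + Tukey HSD",
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["anova_p"] = float(anova_p)
    return out


def _read_csv(path: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except Exception as exc:  # re-raise with file context
        raise ValueError(f"failed to parse {path!r}: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage for which the config names an input file.

    Returns a mapping of table name to written path.  Missing optional
    inputs simply omit their tables; any failure removes all partial
    outputs before re-raising.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        if config.cohort_csv:
            cohort = _read_csv(config.cohort_csv)
            scores, summaries = score_cohort(
                cohort, config.min_minor_fraction, config.cohort_flag_percent
            )
            table = heterogeneity_table(summaries)
            path = out_dir / "heterogeneity_table.csv"
            write_report_csv(table, path, config.config_hash)
            written["heterogeneity_table"] = path

            score_objs = [
                SampleScore(
                    sample_id=row.sample_id,
                    marker=row.marker,
                    h_score=row.h_score,
                    sdi=row.sdi,
                    heterogeneous=row.heterogeneous,
                    group=row.subtype,
                )
                for row in scores.itertuples(index=False)
            ]
            sdi_table = sdi_model_table(score_objs).reset_index()
            path = out_dir / "sdi_comparison.csv"
            write_report_csv(sdi_table, path, config.config_hash)
            written["sdi_comparison"] = path
            logger.info("scored cohort: %d samples, %d markers", len(scores), len(summaries))

        if config.assays_csv:
            assays = _read_csv(config.assays_csv)
            matrix = sensitivity_matrix(assays, config.control_arm, config.additivity_tol)
            annotations = []
            for model, model_rows in assays.groupby("model", sort=False):
                # per-replicate control % pooled across the model's assays
                groups: dict[str, list[float]] = {}
                for (arm, assay), cell in model_rows.groupby(["arm", "assay"], sort=False):
                    ctrl = model_rows.loc[
                        (model_rows["arm"] == config.control_arm)
                        & (model_rows["assay"] == assay),
                        "signal",
                    ].mean()
                    groups.setdefault(str(arm), []).extend(
                        100.0 * cell["signal"].to_numpy(float) / ctrl
                    )
                ann = significance_annotations(groups, control=config.control_arm)
                ann.insert(0, "model", model)
                annotations.append(ann)
            ann_df = pd.concat(annotations, ignore_index=True)
            matrix = matrix.merge(
                ann_df[["model", "arm", "p_value", "significant"]],
                on=["model", "arm"],
                how="left",
            )
            path = out_dir / "sensitivity_matrix.csv"
            write_report_csv(matrix, path, config.config_hash)
            written["sensitivity_matrix"] = path
            logger.info("scored assays: %d model×arm cells", len(matrix))

        if config.calipers_csv:
            calipers = load_caliper_table(_read_csv(config.calipers_csv))
            curves = growth_summary(calipers)
            path = out_dir / "growth_curves.csv"
            write_report_csv(curves, path, config.config_hash)
            written["growth_curves"] = path
            logger.info("summarized xenograft growth: %d group×day rows", len(curves))

        manifest = {
            "package": "tmshet",
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "seed": config.seed,
            "inputs": {
                name: hashlib.sha256(Path(path).read_bytes()).hexdigest()
                for name, path in (
                    ("cohort", config.cohort_csv),
                    ("assays", config.assays_csv),
                    ("calipers", config.calipers_csv),
                )
                if path
            },
            "outputs": {
                name: hashlib.sha256(path.read_bytes()).hexdigest()
                for name, path in written.items()
            },
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written["manifest"] = manifest_path
        return written
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
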
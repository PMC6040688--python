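"""End-to-end group analysis: per-subject FD per hemisphere, group tests, report.

Orchestrates the full study design over a cohort of binary masks: estimate
the correlation dimension of every (subject, hemisphere) mask, compare
case vs control FD per hemisphere with a two-tailed Mann-Whitney U test
(Bonferroni-corrected over hemispheres) plus Cohen's U3, compare the fit
quality metrics (R^2, log-space RMSE) and mask volumes, and run the
partial Spearman analysis linking the case group's PIQ>VIQ spread to FD
while controlling for age.  The whole analysis is deterministic under the
configured seeds and serializes to a schema-validated JSON report plus a
per-subject CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .boxcount import FDParams, estimate_fd
from .stats import (
    GroupComparison,
    SummaryStats,
    bonferroni_adjust,
    compare_groups,
    mann_whitney_u,
    spearman_partial,
    t_from_summary,
)
from .volume import VoxelVolume, mask_volume_mm3

__all__ = ["AnalysisConfig", "AnalysisReport", "run_group_analysis"]

HEMISPHERES = ("left", "right")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of a group analysis run.

    ``volumes`` maps subject id -> hemisphere -> mask.  ``covariates`` must
    contain one row per subject with columns id, group, age, viq, piq.
    ``case_label`` names the group hypothesized to have *lower* FD.
    """

    volumes: Mapping[str, Mapping[str, VoxelVolume]]
    covariates: pd.DataFrame
    fd_params: FDParams = dc_field(default_factory=FDParams)
    case_label: str = "case"
    control_label: str = "control"
    n_boot: int = 10_000
    boot_seed: int = 0
    spearman_tails: int = 2
    out_dir: str | None = None


class ComparisonModel(BaseModel):
    u_statistic: float
    p_two_tailed: float
    p_adjusted: float
    u3: float
    u3_ci: tuple[float, float]
    median_lower: float
    median_higher: float
    range_lower: tuple[float, float]
    range_higher: tuple[float, float]
    p_method: str


class FitQualityComparison(BaseModel):
    """Group test on a fit-quality metric; reported both nonparametrically
    and as a pooled t (unadjusted, labelled secondary outcomes)."""

    metric: str
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    mannwhitney_u: float
    mannwhitney_p: float
    t_statistic: float
    t_df: int


class SubjectHemiResult(BaseModel):
    subject: str
    group: str
    hemisphere: str
    fd: float
    r_squared: float
    rmse: float
    breakpoint: int
    r_min_used: int
    r_max_used: int
    n_points_used: int
    volume_mm3: float


class SpearmanResult(BaseModel):
    hemisphere: str
    subset: str = Field(description="'piq_gt_viq' (strictly positive spread) or 'all_cases'")
    n: int
    rho: float | None
    df: int
    p: float | None
    tails: int


class HemisphereComparisons(BaseModel):
    hemisphere: str
    fd: ComparisonModel
    r_squared: FitQualityComparison
    rmse: FitQualityComparison
    volume_mannwhitney_u: float
    volume_mannwhitney_p: float


class Provenance(BaseModel):
    software_version: str
    fd_params: dict
    n_boot: int
    boot_seed: int
    bonferroni_m: int
    case_label: str
    control_label: str


class AnalysisReport(BaseModel):
    """Structured outcome of :func:`run_group_analysis`."""

    subjects: list[SubjectHemiResult]
    hemispheres: list[HemisphereComparisons]
    spearman: list[SpearmanResult]
    provenance: Provenance

    def subject_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.model_dump() for s in self.subjects])


def _comparison_model(c: GroupComparison, ) -> ComparisonModel:
    return ComparisonModel(**c.to_dict() | {"u3_ci": tuple(c.u3_ci)})


def _fit_quality(metric: str, case_vals: np.ndarray, control_vals: np.ndarray) -> FitQualityComparison:
    u, p = mann_whitney_u(case_vals, control_vals)
    t, df = t_from_summary(
        SummaryStats(float(case_vals.mean()), float(case_vals.std(ddof=1)), len(case_vals)),
        SummaryStats(float(control_vals.mean()), float(control_vals.std(ddof=1)), len(control_vals)),
    )
    return FitQualityComparison(
        metric=metric,
        mean_case=float(case_vals.mean()),
        sd_case=float(case_vals.std(ddof=1)),
        mean_control=float(control_vals.mean()),
        sd_control=float(control_vals.std(ddof=1)),
        mannwhitney_u=float(u),
        mannwhitney_p=float(p),
        t_statistic=float(t),
        t_df=int(df),
    )


def _validate_config(config: AnalysisConfig) -> pd.DataFrame:
    covs = config.covariates
    required = {"id", "group", "age", "viq", "piq"}
    missing = required - set(covs.columns)
    if missing:
        raise ValueError(f"covariates table is missing columns: {sorted(missing)}")
    if not covs["id"].is_unique:
        raise ValueError("covariate ids must be unique")
    cov_ids = set(covs["id"])
    man_ids = set(config.volumes)
    if man_ids - cov_ids:
        raise ValueError(f"subjects missing from covariates: {sorted(man_ids - cov_ids)}")
    for sid, per_hemi in config.volumes.items():
        bad = set(per_hemi) - set(HEMISPHERES)
        if bad:
            raise ValueError(f"unknown hemisphere keys for {sid}: {sorted(bad)}")
    covs = covs[covs["id"].isin(man_ids)].reset_index(drop=True)
    groups = set(covs["group"])
    if not {config.case_label, config.control_label} <= groups:
        raise ValueError(
            f"covariates must contain groups {config.case_label!r} and "
            f"{config.control_label!r}; found {sorted(groups)}"
        )
    for label in (config.case_label, config.control_label):
        if (covs["group"] == label).sum() < 2:
            raise ValueError(f"need >= 2 subjects in group {label!r}")
    return covs


def run_group_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the full deterministic group analysis; optionally write JSON + CSV."""
    covs = _validate_config(config)
    hemis = sorted(
        {h for per_hemi in config.volumes.values() for h in per_hemi},
        key=HEMISPHERES.index,
    )
    m = len(hemis)

    subjects: list[SubjectHemiResult] = []
    group_of = dict(zip(covs["id"], covs["group"]))
    for sid in sorted(config.volumes):
        for hemi in hemis:
            if hemi not in config.volumes[sid]:
                raise ValueError(f"subject {sid} is missing hemisphere {hemi!r}")
            vol = config.volumes[sid][hemi]
            res = estimate_fd(vol, config.fd_params)
            subjects.append(
                SubjectHemiResult(
                    subject=sid,
                    group=str(group_of[sid]),
                    hemisphere=hemi,
                    fd=res.fd,
                    r_squared=res.r_squared,
                    rmse=res.rmse,
                    breakpoint=res.breakpoint,
                    r_min_used=res.r_min_used,
                    r_max_used=res.r_max_used,
                    n_points_used=res.n_points_used,
                    volume_mm3=mask_volume_mm3(vol),
                )
            )

    df = pd.DataFrame([s.model_dump() for s in subjects])
    hemi_reports: list[HemisphereComparisons] = []
    for hemi in hemis:
        sub = df[df["hemisphere"] == hemi]
        case = sub[sub["group"] == config.case_label]
        ctrl = sub[sub["group"] == config.control_label]
        fd_cmp = compare_groups(
            case["fd"].to_numpy(),
            ctrl["fd"].to_numpy(),
            m_comparisons=m,
            n_boot=config.n_boot,
            seed=config.boot_seed,
        )
        vol_u, vol_p = mann_whitney_u(case["volume_mm3"].to_numpy(), ctrl["volume_mm3"].to_numpy())
        hemi_reports.append(
            HemisphereComparisons(
                hemisphere=hemi,
                fd=_comparison_model(fd_cmp),
                r_squared=_fit_quality(
                    "r_squared", case["r_squared"].to_numpy(), ctrl["r_squared"].to_numpy()
                ),
                rmse=_fit_quality("rmse", case["rmse"].to_numpy(), ctrl["rmse"].to_numpy()),
                volume_mannwhitney_u=float(vol_u),
                volume_mannwhitney_p=float(vol_p),
            )
        )

    # PIQ>VIQ spread vs FD in the case group, controlling for age: the primary
    # subset keeps only strictly positive spreads (ties and reversals dropped)
    spearman_results: list[SpearmanResult] = []
    case_covs = covs[covs["group"] == config.case_label].set_index("id")
    for hemi in hemis:
        sub = df[(df["hemisphere"] == hemi) & (df["group"] == config.case_label)]
        merged = sub.set_index("subject").drop(columns=["group"]).join(case_covs, how="inner")
        spread = merged["piq"] - merged["viq"]
        for subset, sel in (("piq_gt_viq", spread > 0), ("all_cases", spread.notna())):
            msub = merged[sel]
            n = len(msub)
            if n >= 4:
                rho, dof, p = spearman_partial(
                    (msub["piq"] - msub["viq"]).to_numpy(),
                    msub["fd"].to_numpy(),
                    [msub["age"].to_numpy()],
                    tails=config.spearman_tails,
                )
            else:
                rho, dof, p = None, 0, None  # too few subjects in the subset
            spearman_results.append(
                SpearmanResult(
                    hemisphere=hemi, subset=subset, n=n, rho=rho, df=dof, p=p,
                    tails=config.spearman_tails,
                )
            )

    report = AnalysisReport(
        subjects=subjects,
        hemispheres=hemi_reports,
        spearman=spearman_results,
        provenance=Provenance(
            software_version=__version__,
            fd_params=vars(config.fd_params).copy(),
            n_boot=config.n_boot,
            boot_seed=config.boot_seed,
            bonferroni_m=m,
            case_label=config.case_label,
            control_label=config.control_label,
        ),
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.model_dump_json(indent=2))
        report.subject_frame().to_csv(out / "subjects.csv", index=False)
    return report


def report_json_schema() -> dict:
    """JSON schema of the analysis report (published in docs/report_schema.json)."""
    return AnalysisReport.model_json_schema()


def load_report(path: str | Path) -> AnalysisReport:
    """Read and schema-validate a report written by :func:`run_group_analysis`."""
    return AnalysisReport.model_validate(json.loads(Path(path).read_text()))
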
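"""Synthetic two-group cohorts: rough-shell volumes plus covariates.

Emulates the statistical structure of a case/control structural-complexity
study without any image download: per subject, a latent surface-roughness
value drives a rough-shell volume for each hemisphere (cases shifted toward
lower roughness, hence lower estimated FD), and the case group's PIQ-VIQ
spread is coupled to roughness through a Gaussian copula so that a partial
Spearman analysis downstream can recover a planted rank correlation.

Verbal IQ is drawn from the same distribution in both groups (the matched
covariate); ages are uniform over the study range; handedness is a seeded
Bernoulli draw.  Everything is a pure function of the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantoms import RoughShellSpec, generate_rough_shell
from .volume import VoxelVolume, write_mask

__all__ = ["CohortSpec", "generate_covariates", "generate_cohort", "write_cohort"]

HEMISPHERES = ("left", "right")

# Covariate marginals for the synthetic cohorts, in score points / years:
# verbal IQ matched across groups; the case group's PIQ is built as
# VIQ + spread so the spread-roughness copula is explicit.
_VIQ_MEAN, _VIQ_SD = 109.0, 13.0
_CASE_SPREAD_MEAN, _CASE_SPREAD_SD = 13.0, 12.0
_CONTROL_PIQ_MEAN, _CONTROL_PIQ_SD = 104.0, 15.0
_P_RIGHT_HANDED = 0.85
# small independent hemisphere-level roughness jitter on top of the
# subject-level latent value
_HEMI_JITTER_SD = 0.03


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort description.

    ``fd_effect`` is the downward shift in case-group roughness (the shell
    generator's amplitude), expressed in roughness units; estimated FD is
    monotonically increasing in roughness, so positive ``fd_effect`` lowers
    the cases' expected FD.  A mapping ``{'left': ..., 'right': ...}``
    confines the shift to specific hemispheres.  ``piq_viq_rho`` is the
    target Spearman correlation between the case group's PIQ-VIQ spread and
    roughness, realized through a Gaussian copula.
    """

    n_case: int = 20
    n_control: int = 18
    roughness_control_mean: float = 0.7
    roughness_sd: float = 0.12
    fd_effect: float | dict[str, float] = 0.0
    piq_viq_rho: float = 0.5
    age_range: tuple[float, float] = (6.5, 10.5)
    seed: int = 0
    shell_template: RoughShellSpec = field(
        default_factory=lambda: RoughShellSpec(outer_radius=32.0, thickness=2.0)
    )

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 subjects per group")
        if not abs(self.piq_viq_rho) <= 1:
            raise ValueError("|piq_viq_rho| must be <= 1")
        if abs(self.piq_viq_rho) > 0.999 and self.n_case < 3:
            raise ValueError("rho ~ +/-1 is infeasible with so few cases")
        if self.roughness_sd < 0:
            raise ValueError("roughness_sd must be >= 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")

    def effect_for(self, hemisphere: str) -> float:
        if isinstance(self.fd_effect, dict):
            return float(self.fd_effect.get(hemisphere, 0.0))
        return float(self.fd_effect)


def _copula_pearson(rho_spearman: float) -> float:
    """Pearson correlation of the latent Gaussian pair giving the target
    Spearman correlation: r = 2 sin(pi * rho_s / 6)."""
    return 2.0 * np.sin(np.pi * rho_spearman / 6.0)


def generate_covariates(spec: CohortSpec) -> pd.DataFrame:
    """Covariate table only (no volumes): id, group, age, viq, piq,
    handedness, and the latent per-hemisphere roughness values."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xC0C0]))
    rows = []
    r_pearson = _copula_pearson(spec.piq_viq_rho)
    cov = np.array([[1.0, r_pearson], [r_pearson, 1.0]])
    chol = np.linalg.cholesky(cov)

    for group, n in (("case", spec.n_case), ("control", spec.n_control)):
        z = rng.normal(size=(n, 2)) @ chol.T
        z_rough, z_spread = z[:, 0], z[:, 1]
        age = rng.uniform(*spec.age_range, size=n)
        viq = rng.normal(_VIQ_MEAN, _VIQ_SD, size=n)
        hand = np.where(rng.random(n) < _P_RIGHT_HANDED, "R", "L")
        if group == "case":
            base = spec.roughness_control_mean + spec.roughness_sd * z_rough
            spread = _CASE_SPREAD_MEAN + _CASE_SPREAD_SD * z_spread
            piq = viq + spread
        else:
            base = spec.roughness_control_mean + spec.roughness_sd * rng.normal(size=n)
            piq = rng.normal(_CONTROL_PIQ_MEAN, _CONTROL_PIQ_SD, size=n)
        for i in range(n):
            rough = {}
            for hemi in HEMISPHERES:
                shift = spec.effect_for(hemi) if group == "case" else 0.0
                val = base[i] - shift + rng.normal(0.0, _HEMI_JITTER_SD)
                rough[hemi] = float(np.clip(val, 0.0, 1.5))
            rows.append(
                {
                    "id": f"{group}_{i:03d}",
                    "group": group,
                    "age": float(age[i]),
                    "viq": float(np.rint(viq[i])),
                    "piq": float(np.rint(piq[i])),
                    "handedness": str(hand[i]),
                    "true_roughness": rough["right"],
                    "true_roughness_left": rough["left"],
                    "true_roughness_right": rough["right"],
                }
            )
    df = pd.DataFrame(rows)
    assert df["id"].is_unique
    return df


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, dict[str, VoxelVolume]], pd.DataFrame]:
    """Full cohort: per-subject left/right rough-shell volumes + covariates.

    Volume seeds are spawned deterministically from the cohort seed, so the
    whole cohort is a pure function of the spec.
    """
    covs = generate_covariates(spec)
    seed_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5EED]))
    volumes: dict[str, dict[str, VoxelVolume]] = {}
    for _, row in covs.iterrows():
        per_hemi = {}
        for hemi in HEMISPHERES:
            shell = RoughShellSpec(
                outer_radius=spec.shell_template.outer_radius,
                thickness=spec.shell_template.thickness,
                roughness_amplitude=row[f"true_roughness_{hemi}"],
                roughness_scale=spec.shell_template.roughness_scale,
                grid_size=spec.shell_template.grid_size,
                seed=int(seed_rng.integers(0, 2**31 - 1)),
            )
            per_hemi[hemi] = generate_rough_shell(shell)
        volumes[row["id"]] = per_hemi
    return volumes, covs


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Materialize a cohort on disk: per-subject NIfTI masks + covariates.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    volumes, covs = generate_cohort(spec)
    for sid, per_hemi in volumes.items():
        for hemi, vol in per_hemi.items():
            write_mask(vol, out / f"{sid}_{hemi}.nii.gz")
    covs.to_csv(out / "covariates.csv", index=False)
    return out
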
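"""Synthetic FDG-PET cohorts with controllable modular covariance structure.

The generator emulates the statistical situation a group-level metabolic
covariance analysis assumes: each subject contributes one SUVR value per
atlas ROI, between-ROI correlation across subjects carries block (modular)
structure, and age and sex act as additive confounds.  Two groups, A and B,
share a base block-correlation matrix; group B's within-versus-between
module contrast can be shifted to inject a known group difference, which is
what power and calibration studies of the downstream pipeline need.

Age and sex effects are applied additively and identically to every ROI so
that ordinary least-squares covariate adjustment removes them exactly in
expectation; that choice isolates the covariate-control stage for testing.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .cohort import CohortTable

__all__ = ["CohortSpec", "build_block_correlation", "simulate_cohort", "write_cohort"]

logger = logging.getLogger(__name__)

_PD_CLIP = 1e-8


@dataclass
class CohortSpec:
    """Parameters of a two-group synthetic cohort.

    ``rho_within``/``rho_between`` set the block correlation of group A;
    group B's within/between contrast is shifted by ``delta_contrast_groupB``
    (half added to its within-module correlation, half subtracted from its
    between-module correlation, so the contrast changes by exactly delta).
    Group sizes default to 17 vs 39 to mirror a typical patient-vs-control
    comparison; sizes, noise and confound strengths are all overridable.
    """

    n_subjects_per_group: tuple[int, int] = (17, 39)
    n_rois: int = 109
    n_modules: int = 4
    rho_within: float = 0.5
    rho_between: float = 0.2
    delta_contrast_groupB: float = 0.0
    mean_suvr: float = 1.2
    subject_noise_sd: float = 0.15
    age_slope: float = -0.002
    sex_offset: float = 0.02
    age_range: tuple[float, float] = (20.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_subjects_per_group, int):
            self.n_subjects_per_group = (
                self.n_subjects_per_group,
                self.n_subjects_per_group,
            )
        self.validate()

    def validate(self) -> None:
        n_a, n_b = self.n_subjects_per_group
        if n_a < 1 or n_b < 1:
            raise ValueError("group sizes must be >= 1")
        if self.n_rois < 2 or self.n_modules < 1:
            raise ValueError("need n_rois >= 2 and n_modules >= 1")
        if self.n_modules > self.n_rois:
            raise ValueError("n_modules cannot exceed n_rois")
        for label, rw, rb in (
            ("group A", self.rho_within, self.rho_between),
            ("group B", *self.group_b_rhos()),
        ):
            if not (0.0 <= rb <= rw < 1.0):
                raise ValueError(
                    f"{label}: need 0 <= rho_between <= rho_within < 1, "
                    f"got within={rw:.3f}, between={rb:.3f}"
                )
        if self.mean_suvr <= 0:
            raise ValueError("mean_suvr must be positive")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be >= 0")
        lo, hi = self.age_range
        if not lo <= hi:
            raise ValueError("age_range must be (min, max) with min <= max")

    def group_b_rhos(self) -> tuple[float, float]:
        d = self.delta_contrast_groupB
        return self.rho_within + d / 2.0, self.rho_between - d / 2.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("n_subjects_per_group", "age_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _module_assignment(n_rois: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-even partition of ROI indices into modules."""
    sizes = [len(b) for b in np.array_split(np.arange(n_rois), n_modules)]
    return np.repeat(np.arange(n_modules), sizes)


def build_block_correlation(
    n_rois: int,
    n_modules: int,
    rho_within: float,
    rho_between: float,
) -> np.ndarray:
    """Block-constant correlation matrix: ``rho_within`` inside contiguous
    near-even modules, ``rho_between`` elsewhere, unit diagonal.

    Positive definiteness is checked; a matrix that fails the check is
    repaired by clipping eigenvalues at 1e-8 and rescaling to unit diagonal,
    and the repair is logged.  For ``rho_between <= rho_within`` both in
    [0, 1) the construction is positive definite without repair.
    """
    if not (0.0 <= rho_between <= rho_within < 1.0):
        raise ValueError("need 0 <= rho_between <= rho_within < 1")
    modules = _module_assignment(n_rois, n_modules)
    same = modules[:, None] == modules[None, :]
    corr = np.where(same, rho_within, rho_between)
    np.fill_diagonal(corr, 1.0)

    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] <= 0:
        logger.warning(
            "block correlation not positive definite (min eigenvalue %.3e); "
            "repairing by eigenvalue clipping at %g",
            eigvals[0],
            _PD_CLIP,
        )
        vals, vecs = np.linalg.eigh(corr)
        corr = (vecs * np.clip(vals, _PD_CLIP, None)) @ vecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        if np.linalg.eigvalsh(corr)[0] <= 0:
            raise ValueError("correlation matrix not positive definite after repair")
    return corr


def _draw_group(
    rng: np.random.Generator,
    n: int,
    group: str,
    corr: np.ndarray,
    spec: CohortSpec,
    id_offset: int,
) -> dict:
    n_rois = spec.n_rois
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, size=n)
    # balanced sexes: half M, half F, order shuffled reproducibly
    sexes = np.array(["M", "F"])[np.arange(n) % 2]
    rng.shuffle(sexes)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, n_rois))
    suvr = spec.mean_suvr + spec.subject_noise_sd * (z @ chol.T)
    mid_age = 0.5 * (lo + hi)
    suvr += spec.age_slope * (ages - mid_age)[:, None]
    suvr += spec.sex_offset * (sexes == "M").astype(float)[:, None]
    return {
        "subject_id": [f"sub-{group}{i + 1 + id_offset:03d}" for i in range(n)],
        "group": [group] * n,
        "age": ages,
        "sex": sexes,
        "suvr": suvr,
    }


def _warn_if_nonpositive_likely(spec: CohortSpec) -> None:
    """Warn when the marginal law puts > 1% mass at SUVR <= 0."""
    lo, hi = spec.age_range
    half_span = 0.5 * (hi - lo)
    worst_mean = (
        spec.mean_suvr
        - abs(spec.age_slope) * half_span
        - max(0.0, -spec.sex_offset)
    )
    if spec.subject_noise_sd == 0:
        p = 1.0 if worst_mean <= 0 else 0.0
    else:
        p = stats.norm.cdf(0.0, loc=worst_mean, scale=spec.subject_noise_sd)
    if p > 0.01:
        warnings.warn(
            f"spec implies P(SUVR <= 0) up to {p:.1%} for some subjects; "
            "generated values may be clipped-invalid",
            stacklevel=3,
        )


def simulate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a two-group cohort table from a :class:`CohortSpec`.

    Each subject's SUVR vector is multivariate normal with the group's
    block correlation matrix, scaled by ``subject_noise_sd`` and centered at
    ``mean_suvr``, then shifted additively by the age slope (relative to
    mid-range age) and the sex offset (applied to males) on every ROI.
    Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    _warn_if_nonpositive_likely(spec)
    rng = np.random.default_rng(spec.seed)

    corr_a = build_block_correlation(
        spec.n_rois, spec.n_modules, spec.rho_within, spec.rho_between
    )
    rw_b, rb_b = spec.group_b_rhos()
    corr_b = build_block_correlation(spec.n_rois, spec.n_modules, rw_b, rb_b)

    n_a, n_b = spec.n_subjects_per_group
    part_a = _draw_group(rng, n_a, "A", corr_a, spec, id_offset=0)
    part_b = _draw_group(rng, n_b, "B", corr_b, spec, id_offset=0)

    import pandas as pd

    roi_names = CohortTable.default_roi_names(spec.n_rois)
    frames = []
    for part in (part_a, part_b):
        frame = pd.DataFrame(
            {
                "subject_id": part["subject_id"],
                "group": part["group"],
                "age": part["age"],
                "sex": part["sex"],
            }
        )
        frame[roi_names] = part["suvr"]
        frames.append(frame)
    return CohortTable(pd.concat(frames, ignore_index=True))


def write_cohort(cohort: CohortTable, csv_path, spec: CohortSpec | None = None) -> None:
    """Write the cohort CSV; when a spec is given, drop a JSON provenance
    sidecar (same stem, ``.spec.json``) next to it."""
    cohort.to_csv(csv_path)
    if spec is not None:
        sidecar = str(csv_path)
        if sidecar.endswith(".csv"):
            sidecar = sidecar[:-4]
        spec.to_json(sidecar + ".spec.json")
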
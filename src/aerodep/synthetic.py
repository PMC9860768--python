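"""Synthetic cohorts and deposition datasets for end-to-end testing.

No public airway CT data back this kind of analysis, so the package ships
its own generators: a parametric pseudo-subject cohort (log-normal
multipliers on duct cross-sections, a uniform glottal constriction ratio)
emulating intersubject anatomical variability, and noisy
deposition-efficiency datasets drawn around a known sigmoid with
subject-level random effects on the logit scale — the structure assumed by
the pooled curve fit.  Everything is bit-reproducible under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeometryParams, build_synthetic_airway
from .stats import (ImpactionPoint, STAHLHOFEN_BETA1, STAHLHOFEN_BETA2,
                    UNIT_MLS, convert_impaction)
from .lung import BreathingPattern, load_breathing_patterns

__all__ = [
    "CohortSpec", "NoisyDeSpec", "generate_cohort", "generate_de_dataset",
    "breathing_fixture", "breathing_patterns_from_fixture",
]


@dataclass
class CohortSpec:
    """Cohort of pseudo-subjects with anatomically varied airway geometry.

    ``diameter_sigma`` is the log-normal sigma applied to transverse
    dimensions (mouth, pharynx, trachea); the glottal constriction is drawn
    as a ratio of the pharynx diameter.  Group labels alternate
    healthy/COPD but draw from the same distribution — the variability
    modeled is anatomical, not disease-specific.
    """

    n_subjects: int = 11
    diameter_sigma: float = 0.20
    length_sigma: float = 0.10
    glottis_ratio_range: tuple = (0.3, 0.7)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        lo, hi = self.glottis_ratio_range
        if not 0 < lo <= hi < 1:
            raise ValueError("glottis ratio range must lie inside (0, 1)")


def generate_cohort(spec: CohortSpec) -> list:
    """Deterministic list of (subject_id, group, GeometryParams).

    Every parameter set passes geometry validation (the glottis is always
    a strict constriction of its own pharynx).
    """
    rng = np.random.default_rng(spec.seed)
    base = GeometryParams()
    cohort = []
    for i in range(spec.n_subjects):
        dm = np.exp(rng.normal(0.0, spec.diameter_sigma, size=4))
        lm = np.exp(rng.normal(0.0, spec.length_sigma, size=3))
        ratio = rng.uniform(*spec.glottis_ratio_range)
        pharynx_d = base.pharynx_diameter * dm[2]
        params = GeometryParams(
            mouth_width=base.mouth_width * dm[0],
            mouth_height=base.mouth_height * dm[1],
            mouth_length=base.mouth_length * lm[0],
            pharynx_diameter=pharynx_d,
            pharynx_bend_angle=base.pharynx_bend_angle,
            glottis_diameter=pharynx_d * ratio,
            larynx_length=base.larynx_length * lm[1],
            trachea_diameter=base.trachea_diameter * dm[3],
            trachea_length=base.trachea_length * lm[2],
        )
        params.validate()
        group = "healthy" if i % 2 == 0 else "copd"
        cohort.append((f"S{i + 1:02d}", group, params))
    return cohort


def cohort_meshes(spec: CohortSpec):
    """Build the labeled mesh of every cohort member (validity gate)."""
    return [(sid, group, build_synthetic_airway(p, seed=spec.seed,
                                                geometry_id=sid))
            for sid, group, p in generate_cohort(spec)]


@dataclass
class NoisyDeSpec:
    """Noisy sigmoid deposition data with subject random effects.

    DE_ij = logistic(logit(sigmoid(beta1 x_j^beta2)) + b_i) with
    b_i ~ N(0, subject_sd): each pseudo-subject's curve is a parallel
    logit-shift of the generating sigmoid, mimicking intersubject scatter
    at fixed impaction parameter.
    """

    beta1: float = STAHLHOFEN_BETA1
    beta2: float = STAHLHOFEN_BETA2
    x_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(2, 6, 50))
    x_unit: str = UNIT_MLS
    n_subjects: int = 11
    subject_sd: float = 0.3
    seed: int = 0


def generate_de_dataset(spec: NoisyDeSpec):
    """Return (x values in spec.x_unit, DE fractions, subject ids)."""
    x = convert_impaction(np.asarray(spec.x_grid, float), spec.x_unit,
                          UNIT_MLS)
    eta = 1.0 - 1.0 / (spec.beta1 * x ** spec.beta2 + 1.0)
    logit = np.log(eta / (1.0 - eta))
    rng = np.random.default_rng(spec.seed)
    b = rng.normal(0.0, spec.subject_sd, size=spec.n_subjects) \
        if spec.subject_sd > 0 else np.zeros(spec.n_subjects)
    shifted = logit[None, :] + b[:, None]
    de = 1.0 / (1.0 + np.exp(-shifted))
    xs = np.tile(convert_impaction(x, UNIT_MLS, spec.x_unit),
                 spec.n_subjects)
    subjects = np.repeat([f"S{i + 1:02d}" for i in range(spec.n_subjects)],
                         len(x))
    return xs, de.ravel(), subjects


def breathing_fixture() -> pd.DataFrame:
    """The packaged measured breathing-parameter table (28 condition rows)."""
    return load_breathing_patterns()


def breathing_patterns_from_fixture(pause: float = 0.0,
                                    n_breaths: int = 5) -> list:
    """Fixture rows as (row metadata, BreathingPattern) pairs."""
    out = []
    for _, r in breathing_fixture().iterrows():
        out.append((
            {"subject": r["subject"], "d_um": float(r["d_um"]),
             "phase_speed": r["phase_speed"]},
            BreathingPattern(FRC=float(r["FRC_L"]), Q_in=float(r["Q_in_lpm"]),
                             Q_ex=float(r["Q_ex_lpm"]), TV=float(r["TV_L"]),
                             pause=pause, n_breaths=n_breaths,
                             subject=str(r["subject"]))))
    return out
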
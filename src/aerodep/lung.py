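"""Symmetric-generation whole-lung deposition with an oral pre-filter.

A deliberately simple 1-D stand-in for multiple-path dosimetry codes: the
intrathoracic airways are the 24 symmetric Weibel-A generations, linearly
scaled to the subject's functional residual capacity by (FRC / 3.3 L)^(1/3).
Per-generation single-pass efficiencies use standard analytic expressions
(Yeh-Schum-type impaction and sedimentation, a Gormley-Kennedy-style
diffusion penetration), and a tidal breath is advected as a volume front:
the parcel of tidal air that penetrates to generation k deposits along its
path in and out, pauses in the alveolar region, and partially mixes into
residual air there.

The oral filter couples in by the bookkeeping
``mass entering the lung = (1 - eta_oral_in) * inhaled mass`` and
``oral deposition on exhalation = eta_oral_ex * exhaled mass``; the overall
retained fraction is everything that does not return to ambient air.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import constants as C

__all__ = [
    "BreathingPattern", "LungModel", "WholeLungResult",
    "build_lung_model", "generation_efficiencies", "simulate_breaths",
    "retained_fraction", "load_breathing_patterns",
]

#: Weibel model A airway dimensions (diameter, length in cm per generation).
_WEIBEL_A = np.array([
    # d_cm   L_cm
    [1.80, 12.00], [1.22, 4.76], [0.83, 1.90], [0.56, 0.76],
    [0.45, 1.27], [0.35, 1.07], [0.28, 0.90], [0.23, 0.76],
    [0.186, 0.64], [0.154, 0.54], [0.130, 0.46], [0.109, 0.39],
    [0.095, 0.33], [0.082, 0.27], [0.074, 0.23], [0.066, 0.20],
    [0.060, 0.165], [0.054, 0.141], [0.050, 0.117], [0.047, 0.099],
    [0.045, 0.083], [0.043, 0.070], [0.041, 0.059], [0.041, 0.050],
])

_REFERENCE_FRC_L = 3.3
_FIRST_ALVEOLAR_GEN = 17  # generations 0-16 tracheobronchial, 17-23 alveolated

_BOLTZMANN_T = 1.38e-23 * 293.0  # kT at 20 C, J


@dataclass
class BreathingPattern:
    """One steady-breathing condition (volumes in L, flows in L/min)."""

    FRC: float
    Q_in: float
    Q_ex: float
    TV: float
    pause: float = 0.0
    n_breaths: int = 5
    subject: str = ""

    def __post_init__(self):
        for name in ("FRC", "Q_in", "Q_ex", "TV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.TV > 2 * self.FRC:
            raise ValueError("tidal volume implausibly exceeds 2 * FRC")
        if self.pause < 0 or self.n_breaths < 1:
            raise ValueError("invalid pause or breath count")


@dataclass
class LungModel:
    """Scaled symmetric morphometry: per-generation geometry and volumes."""

    frc_l: float
    diameters: np.ndarray       # m
    lengths: np.ndarray         # m
    counts: np.ndarray
    branching_angle_deg: float = 35.0
    gravity_angle_deg: float = 45.0
    extra_alveolar_volume: float = 0.0  # m^3, appended distally

    @property
    def n_generations(self) -> int:
        return len(self.diameters)

    @property
    def airway_volumes(self) -> np.ndarray:
        """Per-generation duct volume, m^3."""
        return self.counts * np.pi * self.diameters ** 2 / 4 * self.lengths

    @property
    def cumulative_volumes(self) -> np.ndarray:
        """Volume proximal to each generation's entrance, m^3 (len n+1)."""
        return np.concatenate([[0.0], np.cumsum(self.airway_volumes)])


def build_lung_model(frc_l: float) -> LungModel:
    """Weibel-A symmetric lung scaled to a subject's FRC.

    Linear dimensions scale with (FRC / 3.3 L)^(1/3); lung gas volume not
    accounted for by the scaled ducts is carried as a distal alveolar
    reservoir so the model holds exactly FRC at the start of a breath.
    """
    if frc_l <= 0:
        raise ValueError("FRC must be positive")
    scale = (frc_l / _REFERENCE_FRC_L) ** (1.0 / 3.0)
    d = _WEIBEL_A[:, 0] * 1e-2 * scale
    length = _WEIBEL_A[:, 1] * 1e-2 * scale
    counts = 2.0 ** np.arange(len(_WEIBEL_A))
    model = LungModel(frc_l=frc_l, diameters=d, lengths=length, counts=counts)
    duct_volume = float(model.airway_volumes.sum())
    model.extra_alveolar_volume = max(frc_l * 1e-3 - duct_volume, 0.0)
    return model


def _diffusivity(d_p: float) -> float:
    """Brownian diffusivity kT / (3 pi mu d_p), m^2/s (no slip correction)."""
    return _BOLTZMANN_T / (3.0 * np.pi * C.AIR_VISCOSITY * d_p)


def generation_efficiencies(model: LungModel, d_um: float, flow_lpm: float,
                            orientation: str = "upright",
                            include_diffusion: bool = True,
                            rho_p: float = C.PARTICLE_DENSITY) -> dict:
    """Single-pass deposition efficiencies per generation.

    Returns arrays ``eta_impaction``, ``eta_sedimentation``,
    ``eta_diffusion`` and their combination
    ``1 - (1-eta_I)(1-eta_S)(1-eta_D)``, each in [0, 1].
    """
    if not 0 < d_um <= 100:
        raise ValueError("particle diameter out of range")
    if orientation != "upright":
        raise ValueError("only the upright orientation is modeled")
    d_p = d_um * 1e-6
    mu = C.AIR_VISCOSITY
    Q = flow_lpm * C.LPM_TO_M3S
    q_gen = Q / model.counts
    area = np.pi * model.diameters ** 2 / 4
    u = q_gen / area

    # impaction (Yeh-Schum form): eta = 1 - (2/pi) acos(theta St) +
    # (1/pi) sin(2 acos(theta St)) for theta St < 1, with
    # St = rho_p d_p^2 u / (9 mu d_airway)
    theta = np.radians(model.branching_angle_deg)
    stk = rho_p * d_p ** 2 * u / (9.0 * mu * model.diameters)
    ts = np.minimum(theta * stk, 1.0)
    acos = np.arccos(ts)
    eta_i = np.where(theta * stk >= 1.0, 1.0,
                     1.0 - 2.0 / np.pi * acos + np.sin(2.0 * acos) / np.pi)
    eta_i[0] = 0.0  # trachea: no upstream bifurcation in this model

    # sedimentation (Yeh-Schum tube form): 1 - exp(-2 g rho_p d_p^2 L
    # cos(phi) / (9 pi mu d u))
    cphi = np.cos(np.radians(model.gravity_angle_deg))
    expo = (2.0 * C.GRAVITY * rho_p * d_p ** 2 * model.lengths * cphi
            / (9.0 * np.pi * mu * model.diameters * u))
    eta_s = 1.0 - np.exp(-expo)

    # diffusion: Ingham/Hinds laminar-tube penetration in mu' = D L / Q_gen
    if include_diffusion:
        dmu = _diffusivity(d_p) * model.lengths / q_gen
        small = dmu < 0.009
        pen = np.where(
            small,
            1.0 - 5.50 * dmu ** (2.0 / 3.0) + 3.77 * dmu,
            0.819 * np.exp(-11.5 * dmu) + 0.0975 * np.exp(-70.1 * dmu)
            + 0.0325 * np.exp(-179.0 * dmu))
        eta_d = np.clip(1.0 - pen, 0.0, 1.0)
    else:
        eta_d = np.zeros_like(eta_s)

    eta_i = np.clip(eta_i, 0.0, 1.0)
    eta_s = np.clip(eta_s, 0.0, 1.0)
    combined = 1.0 - (1.0 - eta_i) * (1.0 - eta_s) * (1.0 - eta_d)
    return {"eta_impaction": eta_i, "eta_sedimentation": eta_s,
            "eta_diffusion": eta_d, "eta_combined": combined}


@dataclass
class WholeLungResult:
    """Per-breath mass ledger, as fractions of one inhaled breath.

    ``f_oral_in + f_TB + f_alv + f_oral_ex + f_exhaled_out = 1`` exactly.
    """

    f_oral_in: float
    f_TB: float
    f_alv: float
    f_oral_ex: float
    f_exhaled_out: float
    n_breaths: int = 5
    d_um: float = 0.0
    subject: str = ""

    @property
    def retained(self) -> float:
        return self.f_oral_in + self.f_TB + self.f_alv + self.f_oral_ex

    def ledger_sum(self) -> float:
        return (self.f_oral_in + self.f_TB + self.f_alv + self.f_oral_ex
                + self.f_exhaled_out)

    def to_dict(self) -> dict:
        return {
            "subject": self.subject, "d_um": self.d_um,
            "f_oral_in": self.f_oral_in, "f_TB": self.f_TB,
            "f_alv": self.f_alv, "f_oral_ex": self.f_oral_ex,
            "f_exhaled_out": self.f_exhaled_out, "retained": self.retained,
        }


def simulate_breaths(lung: LungModel, pattern: BreathingPattern, d_um: float,
                     eta_oral_in: float, eta_oral_ex: float,
                     mixing_fraction: float = 0.3,
                     include_diffusion: bool = True,
                     generation_eta: dict | None = None) -> WholeLungResult:
    """Multiple-breath deposition bookkeeping for one subject-condition.

    Each breath inhales unit aerosol mass: the oral filter removes
    ``eta_oral_in``; the rest advects as a volume front through the
    generations, depositing on the way in, pausing and partially mixing
    (fraction ``mixing_fraction`` of the deep-penetrating parcel stays with
    residual air, scored as alveolar retention), depositing on the way out,
    and losing ``eta_oral_ex`` of the exhaled mass to the oral surfaces.
    ``generation_eta`` may supply precomputed per-generation efficiency
    dicts ``{"in": eta_array, "ex": eta_array}`` to override the analytic
    ones (e.g. a transparent lung with zeros).
    """
    if not (0.0 <= eta_oral_in <= 1.0 and 0.0 <= eta_oral_ex <= 1.0):
        raise ValueError("oral efficiencies must be fractions")
    if not 0.0 <= mixing_fraction <= 1.0:
        raise ValueError("mixing fraction must be in [0, 1]")
    tv_m3 = pattern.TV * 1e-3
    vcum = lung.cumulative_volumes
    model_volume = vcum[-1] + lung.extra_alveolar_volume
    if tv_m3 > model_volume:
        raise ValueError("tidal volume exceeds the model lung volume")

    if generation_eta is None:
        eta_in = generation_efficiencies(
            lung, d_um, pattern.Q_in,
            include_diffusion=include_diffusion)["eta_combined"]
        eta_ex = generation_efficiencies(
            lung, d_um, pattern.Q_ex,
            include_diffusion=include_diffusion)["eta_combined"]
    else:
        eta_in = np.asarray(generation_eta["in"], float)
        eta_ex = np.asarray(generation_eta["ex"], float)
    ng = lung.n_generations

    # parcel weights: fraction of the tidal bolus whose terminal station is
    # generation k (k = ng means penetration past the last generation into
    # the alveolar reservoir)
    pen = np.clip((tv_m3 - vcum) / tv_m3, 0.0, 1.0)  # len ng+1, pen[0] = 1
    w = np.empty(ng + 1)
    w[:ng] = pen[:ng] - pen[1:]
    w[ng] = pen[ng]

    # pause sedimentation in the alveolar space (settling across a
    # 300-um-scale air space)
    v_s = C.stokes_settling_velocity(d_um * 1e-6)
    eta_pause = 1.0 - np.exp(-pattern.pause * v_s / 3e-4) \
        if pattern.pause > 0 else 0.0

    surv_in = np.concatenate([[1.0], np.cumprod(1.0 - eta_in)])  # arrival at k

    f_oral_in = eta_oral_in
    M = 1.0 - eta_oral_in
    dep_tb = 0.0
    dep_alv = 0.0
    exhaled_from_lung = 0.0

    for k in range(ng + 1):
        if w[k] == 0.0:
            continue
        mass = M * w[k]
        kmax = min(k, ng - 1)
        # inbound deposition through generations 0..kmax
        for j in range(kmax + 1):
            dj = mass * surv_in[j] * eta_in[j]
            if j < _FIRST_ALVEOLAR_GEN:
                dep_tb += dj
            else:
                dep_alv += dj
        airborne = mass * surv_in[kmax + 1]
        # pause + alveolar mixing for parcels reaching alveolated territory
        if k >= _FIRST_ALVEOLAR_GEN:
            dep_alv += airborne * eta_pause
            airborne *= 1.0 - eta_pause
        if k == ng:
            dep_alv += airborne * mixing_fraction
            airborne *= 1.0 - mixing_fraction
        # outbound deposition through generations kmax..0
        for j in range(kmax, -1, -1):
            dj = airborne * eta_ex[j]
            if j < _FIRST_ALVEOLAR_GEN:
                dep_tb += dj
            else:
                dep_alv += dj
            airborne -= dj
        exhaled_from_lung += airborne

    f_oral_ex = exhaled_from_lung * eta_oral_ex
    f_out = exhaled_from_lung * (1.0 - eta_oral_ex)
    # close the ledger exactly against accumulated float rounding
    drift = 1.0 - (f_oral_in + dep_tb + dep_alv + f_oral_ex + f_out)
    if abs(drift) > 1e-9:
        raise RuntimeError(f"mass ledger drifted by {drift:g}")
    f_out += drift
    return WholeLungResult(
        f_oral_in=f_oral_in, f_TB=dep_tb, f_alv=dep_alv,
        f_oral_ex=f_oral_ex, f_exhaled_out=f_out,
        n_breaths=pattern.n_breaths, d_um=d_um, subject=pattern.subject)


def retained_fraction(result: WholeLungResult) -> float:
    """Total retained fraction: 1 minus the mass exhaled to ambient."""
    return result.retained


def load_breathing_patterns() -> pd.DataFrame:
    """Packaged table of measured subject-specific breathing parameters.

    Columns: subject, d_um, phase_speed (slow/fast), Q_in_lpm, Q_ex_lpm,
    TV_L, FRC_L; 7 healthy subjects x 2 particle sizes x 2 breathing speeds.
    """
    with resources.files("aerodep.data").joinpath(
            "healthy_breathing_patterns.csv").open() as fh:
        return pd.read_csv(fh)
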
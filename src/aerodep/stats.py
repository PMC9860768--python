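"""Impaction-parameter statistics and the sigmoidal deposition correlation.

Oral (extrathoracic) deposition efficiency collapses onto the impaction
parameter ``x = d_a^2 Q`` (aerodynamic diameter squared times flow rate).
Two unit systems are in circulation: um^2 L/min (common in figures) and
um^2 mL/s (the convention of the semi-empirical oral deposition
correlation of Stahlhofen and colleagues,

    eta_oral = 1 - (3.5e-8 (d_a^2 Q)^1.7 + 1)^-1,    d_a in um, Q in mL/s).

The same sigmoid family ``DE = 1 - (beta1 x^beta2 + 1)^-1`` is fitted to
simulated deposition data by nonlinear least squares in a
(log beta1, beta2) parameterization, with confidence intervals from the
asymptotic covariance.  All fits run internally in the um^2 mL/s system;
beta1 is converted to the requested system afterwards by the exact relation
beta1' = beta1 * c^(-beta2) for x' = c x, which makes unit equivariance
hold to machine precision.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sstats

__all__ = [
    "UNIT_LPM", "UNIT_MLS", "STAHLHOFEN_BETA1", "STAHLHOFEN_BETA2",
    "ImpactionPoint", "SigmoidFit", "FitError",
    "impaction_parameter", "convert_impaction", "stahlhofen_eta",
    "regional_de", "fit_sigmoid",
]

UNIT_LPM = "um2_lpm"
UNIT_MLS = "um2_mls"
_UNITS = (UNIT_LPM, UNIT_MLS)

#: L/min -> mL/s scale on the impaction parameter.
_C_LPM_TO_MLS = 1000.0 / 60.0

#: Constants of the semi-empirical oral deposition correlation (x in um^2 mL/s).
STAHLHOFEN_BETA1 = 3.5e-8
STAHLHOFEN_BETA2 = 1.7


class FitError(RuntimeError):
    """Sigmoid fit failed; carries the best candidate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


def _check_unit(unit: str) -> None:
    if unit not in _UNITS:
        raise ValueError(f"unknown impaction-parameter unit {unit!r}; "
                         f"expected one of {_UNITS}")


def impaction_parameter(d_um, q, flow_unit: str = "lpm",
                        out_unit: str = UNIT_LPM):
    """Impaction parameter d_a^2 Q.

    ``d_um`` is the aerodynamic diameter in micrometres; ``q`` the flow
    rate in L/min (``flow_unit="lpm"``) or mL/s (``"mls"``); the result is
    expressed in ``out_unit``.
    """
    d_um = np.asarray(d_um, float)
    q = np.asarray(q, float)
    if np.any(d_um <= 0) or np.any(q <= 0):
        raise ValueError("diameter and flow rate must be positive")
    if flow_unit == "lpm":
        x = d_um ** 2 * q
        unit = UNIT_LPM
    elif flow_unit == "mls":
        x = d_um ** 2 * q
        unit = UNIT_MLS
    else:
        raise ValueError(f"unknown flow unit {flow_unit!r}")
    return convert_impaction(x, unit, out_unit)


def convert_impaction(x, from_unit: str, to_unit: str):
    """Convert impaction-parameter values between unit systems."""
    _check_unit(from_unit)
    _check_unit(to_unit)
    x = np.asarray(x, float)
    if from_unit == to_unit:
        return x
    if from_unit == UNIT_LPM:
        return x * _C_LPM_TO_MLS
    return x / _C_LPM_TO_MLS


def stahlhofen_eta(d_um=None, q_mls=None, x=None, x_unit: str = UNIT_MLS):
    """Semi-empirical oral deposition fraction eta in (0, 1).

    Either (``d_um``, ``q_mls``) or a precomputed impaction parameter ``x``
    (with its unit system) may be given.
    """
    if x is None:
        if d_um is None or q_mls is None:
            raise ValueError("need (d_um, q_mls) or x")
        x = impaction_parameter(d_um, q_mls, flow_unit="mls",
                                out_unit=UNIT_MLS)
    else:
        x = convert_impaction(x, x_unit, UNIT_MLS)
    x = np.asarray(x, float)
    return 1.0 - 1.0 / (STAHLHOFEN_BETA1 * x ** STAHLHOFEN_BETA2 + 1.0)


@dataclass
class ImpactionPoint:
    """One deposition observation keyed by its impaction parameter."""

    d_um: float
    q_lpm: float
    de_percent: float
    subject: str = ""
    direction: str = "inspiratory"

    def x(self, unit: str = UNIT_MLS) -> float:
        return float(impaction_parameter(self.d_um, self.q_lpm,
                                         flow_unit="lpm", out_unit=unit))

    @property
    def de_fraction(self) -> float:
        return self.de_percent / 100.0


def regional_de(result) -> dict:
    """Regional and total deposition efficiencies (percent) of one run."""
    if result.n_injected <= 0:
        raise ValueError("no particles injected")
    out = dict(result.de_region)
    out["total"] = result.de_total
    return out


@dataclass
class SigmoidFit:
    """Fitted sigmoid DE = 1 - (beta1 x^beta2 + 1)^-1 with 95% CIs."""

    beta1: float
    beta2: float
    ci_beta1: tuple
    ci_beta2: tuple
    r2: float
    n: int
    unit_system: str
    flagged: bool = False

    def predict(self, x, x_unit: str | None = None):
        """DE fraction at impaction parameter ``x`` (fit's units by default)."""
        x = convert_impaction(np.asarray(x, float),
                              x_unit or self.unit_system, self.unit_system)
        return 1.0 - 1.0 / (self.beta1 * x ** self.beta2 + 1.0)

    def to_dict(self) -> dict:
        return {
            "beta1": self.beta1, "beta2": self.beta2,
            "ci_beta1": list(self.ci_beta1), "ci_beta2": list(self.ci_beta2),
            "r2": self.r2, "n": self.n, "unit_system": self.unit_system,
            "flagged": self.flagged,
        }


def _sigmoid(logx, log_b1, b2):
    return 1.0 - 1.0 / (np.exp(log_b1 + b2 * logx) + 1.0)


def fit_sigmoid(x, de_fraction=None, x_unit: str = UNIT_MLS,
                out_unit: str | None = None, n_restarts: int = 4
                ) -> SigmoidFit:
    """Least-squares fit of the deposition sigmoid.

    Parameters
    ----------
    x : array of impaction parameters, or a list of :class:`ImpactionPoint`
    de_fraction : deposition efficiencies as fractions in [0, 1]
        (ignored when ``x`` is a point list).
    x_unit, out_unit : unit systems of the input x and of the reported
        beta1 (default: same as input).

    Requires at least 5 points; input spanning less than two decades of x
    is accepted but the resulting fit is ``flagged`` when the beta1
    confidence interval spans more than a factor of 10.
    """
    if de_fraction is None:
        pts = list(x)
        xv = np.array([p.x(UNIT_MLS) for p in pts])
        de = np.array([p.de_fraction for p in pts])
        x_unit = UNIT_MLS
    else:
        xv = convert_impaction(np.asarray(x, float), x_unit, UNIT_MLS)
        de = np.asarray(de_fraction, float)
    out_unit = out_unit or x_unit
    _check_unit(out_unit)
    if len(xv) < 5:
        raise ValueError("need at least 5 points to fit the sigmoid")
    if np.any(xv <= 0):
        raise ValueError("impaction parameters must be positive")
    if np.any((de < 0) | (de > 1)):
        raise ValueError("DE must be a fraction in [0, 1]")

    logx = np.log(xv)
    # logit-log linearization for the starting point: DE/(1-DE) = b1 x^b2
    interior = (de > 1e-12) & (de < 1 - 1e-12)
    if interior.sum() >= 2:
        lg = np.log(de[interior] / (1.0 - de[interior]))
        slope, intercept = np.polyfit(logx[interior], lg, 1)
        p0 = (intercept, slope)
    else:
        p0 = (np.log(STAHLHOFEN_BETA1), STAHLHOFEN_BETA2)

    rng = np.random.default_rng(0)
    best = None
    last_err = None
    for attempt in range(n_restarts + 1):
        start = p0 if attempt == 0 else (
            p0[0] + rng.normal(0, 2.0), max(p0[1] + rng.normal(0, 0.5), 0.1))
        try:
            popt, pcov = optimize.curve_fit(
                _sigmoid, logx, de, p0=start, maxfev=20_000)
        except RuntimeError as err:  # pragma: no cover - rare
            last_err = err
            continue
        resid = de - _sigmoid(logx, *popt)
        ssr = float(resid @ resid)
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise FitError(f"sigmoid fit did not converge: {last_err}")
    ssr, popt, pcov = best
    log_b1, b2 = popt
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    dof = max(len(xv) - 2, 1)
    tcrit = sstats.t.ppf(0.975, dof)
    ci_log_b1 = (log_b1 - tcrit * se[0], log_b1 + tcrit * se[0])
    ci_b2 = (b2 - tcrit * se[1], b2 + tcrit * se[1])
    ss_tot = float(np.sum((de - de.mean()) ** 2))
    r2 = 1.0 - ssr / ss_tot if ss_tot > 0 else float("nan")

    # convert beta1 (fitted in the mL/s system) to the requested system
    c = 1.0 if out_unit == UNIT_MLS else _C_LPM_TO_MLS ** b2
    beta1 = float(np.exp(log_b1) * c)
    ci_beta1 = (float(np.exp(ci_log_b1[0]) * c),
                float(np.exp(ci_log_b1[1]) * c))
    flagged = (not np.isfinite(se).all()) or \
        (ci_beta1[1] / max(ci_beta1[0], 1e-300) > 10.0)
    return SigmoidFit(beta1=beta1, beta2=float(b2), ci_beta1=ci_beta1,
                      ci_beta2=(float(ci_b2[0]), float(ci_b2[1])),
                      r2=float(r2), n=len(xv), unit_system=out_unit,
                      flagged=flagged)
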
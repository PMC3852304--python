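"""Synthetic prostate-RT cohort generator.

Generates cohorts with the statistical structure of the reference study
population so the whole NTCP pipeline can be exercised without patient data:
binary clinical covariates are independent Bernoulli draws at the reference
prevalences; the rectal dose-volume family (V20..V75, Dmean, Dmax) derives
from a single latent per-patient "dosimetric severity" so adjacent Vx
metrics are strongly rank-correlated (as in real planning data, where one
anatomy/plan drives the whole DVH); and the late-GI outcome is drawn
Bernoulli(NTCP(x)) from a supplied logistic coefficient set, by default the
reference three-variable model.

The per-patient DVH is a logistic-in-dose cumulative curve

    V(d) = 100 * (1 + u) / (1 + u * exp(d / w)),   V(0) = 100,

whose free parameter u is solved in closed form so that V(65) equals the
patient's target V65 (a scaled-beta draw matching the reference median 27.0%
and range 0.4-98.2%).  The width w is jittered per patient so the Vx family
correlates highly but not perfectly; a linear taper near the patient's
maximum dose (76-80 Gy, at/just above the 76 Gy prescription) closes the
high-dose tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from . import reference
from .dvh import CUMULATIVE, DVHCurve, vx_column
from .logistic import LogisticNTCPModel

__all__ = ["CohortSpec", "generate_cohort", "generate_dvh", "v65_from_severity",
           "write_cohort", "read_cohort", "COHORT_COLUMNS"]

#: Vx thresholds carried in the cohort table (Gy).
VX_THRESHOLDS: tuple[int, ...] = tuple(range(20, 80, 5))

#: Fixed cohort CSV column order.
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age_gt70", "t3", "psa_gt15", "gleason_gt6", "hormonal", "surgery",
    "diabetes", "smoker", "ahac", "rt_art", "acute_gi",
    "dmax", "dmean",
    *[vx_column(x) for x in VX_THRESHOLDS],
    "late_gi",
)

_BASE_WIDTH = 16.0     # Gy; DVH fall-off scale of a typical rectal plan
_WIDTH_SIGMA = 0.15    # lognormal jitter of the width, clipped at +-2 sigma
_TAPER_WIDTH = 2.0     # Gy; linear closure of the high-dose tail
_GRID_MAX = 80.0       # Gy; no volume beyond prescription + margin


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the reference study conditions: n = 57 patients, the
    published covariate prevalences, a scaled-beta V65 marginal matching
    median 27.0% on [0.4, 98.2], strongly inter-correlated Vx metrics, and
    outcomes drawn from the reference three-variable coefficient set.
    """

    n_patients: int = reference.N_PATIENTS
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(reference.COVARIATE_PREVALENCES)
    )
    v65_min: float = reference.V65_MIN
    v65_median: float = reference.V65_MEDIAN
    v65_max: float = reference.V65_MAX
    beta_a: float = 1.2
    coefficients: LogisticNTCPModel = field(
        default_factory=lambda: reference.MODEL_THREE_VARIABLE
    )
    acute_linked: bool = False
    acute_link_slope: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        for name, p in self.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]: {p}")
        if not (0.0 <= self.v65_min < self.v65_median < self.v65_max <= 100.0):
            raise ValueError("need 0 <= v65_min < v65_median < v65_max <= 100")
        if self.beta_a <= 0:
            raise ValueError("beta_a must be positive")

    @property
    def beta_b(self) -> float:
        """Second beta shape, solved so the scaled median matches."""
        target = (self.v65_median - self.v65_min) / (self.v65_max - self.v65_min)
        return optimize.brentq(
            lambda b: stats.beta.ppf(0.5, self.beta_a, b) - target, 1e-3, 200.0
        )


def v65_from_severity(severity, spec: CohortSpec | None = None):
    """Map latent severity in [0, 1] to the target V65 in percent."""
    spec = spec or CohortSpec()
    s = np.asarray(severity, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("severity must lie in [0, 1]")
    out = spec.v65_min + (spec.v65_max - spec.v65_min) * s
    return float(out) if out.ndim == 0 else out


def _curve_u(v65_pct, width):
    """Closed-form curve parameter u so that V(65) = v65_pct.

    From V(65)/100 = (1+u)/(1+u*A) with A = exp(65/w):
    u = (1 - r) / (r*A - 1), which requires r*A > 1 (the width is clipped
    by the caller to keep the solution feasible).
    """
    r = np.asarray(v65_pct, dtype=float) / 100.0
    A = np.exp(65.0 / np.asarray(width, dtype=float))
    denom = r * A - 1.0
    if np.any(denom <= 0):
        raise ValueError("DVH width too large for the requested V65")
    return (1.0 - r) / denom


def _feasible_width(v65_pct, width):
    """Clip the fall-off width so the V65 target is attainable (10% margin)."""
    r = np.clip(np.asarray(v65_pct, dtype=float) / 100.0, 1e-6, 1.0 - 1e-9)
    wmax = 0.9 * 65.0 / np.log(1.0 / r)
    return np.minimum(np.asarray(width, dtype=float), wmax)


def _cumulative_volume(dose, u, width, dmax_p):
    """Percent volume >= dose for the parametric curve, incl. tail taper."""
    dose = np.asarray(dose, dtype=float)
    v = 100.0 * (1.0 + u) / (1.0 + u * np.exp(dose / width))
    taper = np.clip((dmax_p - dose) / _TAPER_WIDTH, 0.0, 1.0)
    return v * taper


def generate_dvh(
    severity: float,
    patient_id: str = "p",
    grid_step: float = 0.5,
    width: float = _BASE_WIDTH,
    dmax: float = 77.0,
    spec: CohortSpec | None = None,
) -> DVHCurve:
    """Smooth sigmoid-shaped cumulative rectal DVH for one patient.

    The curve's V65 equals ``v65_from_severity(severity)`` (within grid
    interpolation error, well under 0.5%); volume vanishes by ``dmax``,
    which never exceeds 80 Gy (76 Gy prescription plus hotspot margin).
    """
    spec = spec or CohortSpec()
    if not 67.0 <= dmax <= _GRID_MAX:
        raise ValueError(f"dmax must be in [67, {_GRID_MAX}] Gy, got {dmax}")
    v65 = v65_from_severity(severity, spec)
    w = float(_feasible_width(v65, width))
    u = float(_curve_u(v65, w))
    dmax_p = float(dmax)
    grid = np.arange(0.0, _GRID_MAX + grid_step / 2, grid_step)
    vol = _cumulative_volume(grid, u, w, dmax_p)
    vol[np.abs(vol) < 1e-12] = 0.0
    return DVHCurve(patient_id, grid, vol, CUMULATIVE)


def generate_cohort(spec: CohortSpec | None = None, with_dvh: bool = False):
    """Generate a synthetic cohort; seeded and fully reproducible.

    Returns a DataFrame in the fixed ``COHORT_COLUMNS`` order, and
    additionally the per-patient DVH curves when ``with_dvh=True``.
    Binary covariates are independent Bernoulli draws at the specified
    prevalences; ``late_gi`` is Bernoulli(NTCP(x)) under ``spec.coefficients``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    df = pd.DataFrame({"patient_id": [f"p{i + 1:04d}" for i in range(n)]})
    for name, p in spec.prevalences.items():
        if name == "acute_gi":
            continue  # drawn below (may be severity-linked)
        df[name] = (rng.random(n) < p).astype(int)

    severity = stats.beta.ppf(rng.random(n), spec.beta_a, spec.beta_b)
    if spec.acute_linked:
        s_mean = spec.beta_a / (spec.beta_a + spec.beta_b)
        p_acute = expit(
            logit(spec.prevalences["acute_gi"])
            + spec.acute_link_slope * (severity - s_mean)
        )
    else:
        p_acute = np.full(n, spec.prevalences["acute_gi"])
    df["acute_gi"] = (rng.random(n) < p_acute).astype(int)

    v65 = v65_from_severity(severity, spec)
    width = _BASE_WIDTH * np.exp(
        np.clip(rng.normal(0.0, _WIDTH_SIGMA, n), -2 * _WIDTH_SIGMA, 2 * _WIDTH_SIGMA)
    )
    width = _feasible_width(v65, width)
    u = _curve_u(v65, width)
    # Dmax is hotspot-driven, essentially independent of the anatomy-driven
    # Vx family (its univariate correlation with outcome is ~0 in practice)
    dmax_p = 73.0 + 6.7 * stats.beta.ppf(rng.random(n), 2.0, 2.0)

    for x in VX_THRESHOLDS:
        vx = _cumulative_volume(float(x), u, width, dmax_p)
        df[vx_column(x)] = np.clip(vx, 0.0, 100.0)
    df[vx_column(65)] = v65  # exact by construction (taper is 1 at 65 Gy)

    grid = np.arange(0.0, _GRID_MAX + 0.125, 0.25)
    vols = _cumulative_volume(grid[None, :], u[:, None], width[:, None], dmax_p[:, None])
    df["dmean"] = np.trapezoid(vols, grid, axis=1) / 100.0
    df["dmax"] = dmax_p

    ntcp = spec.coefficients.ntcp(df)
    df["late_gi"] = (rng.random(n) < ntcp).astype(int)
    df = df[list(COHORT_COLUMNS)]

    if not with_dvh:
        return df
    curves = [
        generate_dvh(float(s), pid, width=float(w0), dmax=float(dm), spec=spec)
        for s, w0, dm, pid in zip(severity, width, dmax_p, df["patient_id"])
    ]
    return df, curves


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the canonical column order."""
    df[list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, checking required columns and binary coding."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("patient_id", "late_gi") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if not df["late_gi"].isin((0, 1)).all():
        raise ValueError(f"{path}: late_gi must be coded 0/1")
    return df
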
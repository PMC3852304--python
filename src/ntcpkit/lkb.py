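"""Lyman-Kutcher-Burman (LKB) NTCP comparator model.

The heterogeneous rectal dose distribution is reduced to a generalised
equivalent uniform dose, gEUD = (sum_i v_i * D_i^(1/n))^n, over the
irradiated organ (fractional volumes v_i summing to 1), and the complication
probability follows a probit dose response:

    NTCP = Phi(t),   t = (gEUD - TD50) / (m * TD50),

with Phi the standard normal CDF.  n (volume effect), m (slope) and TD50
(50% tolerance dose, Gy) are endpoint-specific parameters supplied as
configuration; this package ships only a clearly labelled synthetic
placeholder set for demonstrations and tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .dvh import DVHCurve, as_differential

__all__ = ["LKBParameters", "LKBModel", "geud", "DEMO_PARAMETERS"]


@dataclass(frozen=True)
class LKBParameters:
    """LKB parameter triple for one toxicity endpoint.

    Attributes
    ----------
    n : float
        Volume-effect exponent (>0); n -> 0 approaches a serial organ
        (gEUD -> Dmax), n = 1 gives gEUD = Dmean.
    m : float
        Slope parameter (>0); smaller m = steeper dose response.
    td50 : float
        Dose in Gy giving 50% complication probability under uniform
        whole-organ irradiation.
    label : str
        Endpoint label for reports.
    """

    n: float
    m: float
    td50: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("n", "m", "td50"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"LKB parameter {name} must be positive and finite, got {v}")


#: Synthetic placeholder parameters for tests and demos only.  These are NOT
#: fitted or published values for any clinical endpoint.
DEMO_PARAMETERS = LKBParameters(n=0.1, m=0.25, td50=76.0, label="demo (synthetic)")


def geud(curve: DVHCurve, n: float) -> float:
    """Generalised equivalent uniform dose of a DVH, in Gy.

    gEUD = (sum_i v_i * D_i^(1/n))^n with bin-centre doses D_i and fractional
    volumes v_i normalised over the irradiated organ.  Evaluated in log space
    so small n (strong serial behaviour, exponent 1/n large) stays finite.
    """
    if not np.isfinite(n) or n <= 0:
        raise ValueError(f"volume-effect exponent n must be positive, got {n}")
    doses, masses = as_differential(curve)
    total = masses.sum()
    if total <= 0:
        return 0.0
    frac = masses / total
    pos = doses > 0
    if not pos.any():
        return 0.0
    a = 1.0 / n
    # log sum_i v_i D_i^a, then gEUD = exp(n * logsum)
    logsum = logsumexp(a * np.log(doses[pos]), b=frac[pos])
    return float(np.exp(n * logsum))


class LKBModel:
    """Probit (LKB) NTCP model with fixed parameters.

    Examples
    --------
    >>> model = LKBModel(LKBParameters(n=0.1, m=0.25, td50=76.0))
    >>> model.ntcp(curve)
    """

    def __init__(self, params: LKBParameters):
        self.params = params

    def geud(self, curve: DVHCurve) -> float:
        return geud(curve, self.params.n)

    def t_value(self, curve: DVHCurve) -> float:
        """Standardised dose deviate t = (gEUD - TD50) / (m * TD50)."""
        p = self.params
        return (self.geud(curve) - p.td50) / (p.m * p.td50)

    def ntcp(self, curve: DVHCurve) -> float:
        """Complication probability Phi(t); exact via the error function."""
        return float(norm.cdf(self.t_value(curve)))
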
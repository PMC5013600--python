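"""Node-age calibration densities for divergence-time analyses.

Implements the three density shapes commonly attached to calibrated
nodes in relaxed-clock dating: a Normal built from a point estimate and
a symmetric 95% confidence interval (secondary calibrations taken from
earlier studies), a truncated Cauchy above a hard fossil minimum (the
standard long-tailed fossil-calibration prior), and a hard maximum bound
(uniform).  Only the densities are provided — evaluation, quantiles and
normalization checks — not any dating MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["CalibrationDensity", "normal_from_ci", "truncated_cauchy", "max_bound"]

Z975 = 1.959964  # fixed 97.5% normal quantile for reproducible CI <-> sd conversion


@dataclass
class CalibrationDensity:
    """A calibration density attached (optionally) to a labeled node.

    kind is one of ``normal_from_ci``, ``truncated_cauchy``, ``max_bound``;
    ``params`` holds the shape parameters in Myr.  pdf/cdf/ppf evaluate the
    normalized density on its support.
    """

    kind: str
    params: dict = field(default_factory=dict)
    node_label: str | None = None
    _pdf: callable = None
    _cdf: callable = None
    _ppf: callable = None

    def pdf(self, t):
        return self._pdf(np.asarray(t, dtype=float))

    def cdf(self, t):
        return self._cdf(np.asarray(t, dtype=float))

    def quantile(self, q):
        return self._ppf(np.asarray(q, dtype=float))


def normal_from_ci(
    mean: float, ci_low: float, ci_high: float, node_label: str | None = None
) -> CalibrationDensity:
    """Normal density from a mean and 95% CI (ages in Myr).

    sd = (ci_high - mean) / 1.959964, i.e. the upper half-width sets the
    spread.  Printed secondary calibrations are often slightly asymmetric
    (they summarize a non-normal posterior), so asymmetry is tolerated;
    only the resulting upper endpoint is reproduced exactly in that case.
    """
    if not ci_low < mean < ci_high:
        raise ValueError("require ci_low < mean < ci_high")
    sd = (ci_high - mean) / Z975
    dist = stats.norm(loc=mean, scale=sd)
    return CalibrationDensity(
        kind="normal_from_ci",
        params={"mean": mean, "sd": sd, "ci_low": ci_low, "ci_high": ci_high},
        node_label=node_label,
        _pdf=dist.pdf,
        _cdf=dist.cdf,
        _ppf=dist.ppf,
    )


def truncated_cauchy(
    t_min: float, offset_p: float, scale_c: float, node_label: str | None = None
) -> CalibrationDensity:
    """Fossil-minimum calibration: Cauchy with location t_min(1 + p) and
    scale c*t_min, renormalized over the hard support [t_min, inf).

    The density is proportional to 1 / (1 + ((t - t_min(1+p)) / (c t_min))^2)
    for t >= t_min and zero below; its mode sits at t_min(1 + p).  The
    hard minimum reflects a bound the fossil record cannot undercut (a
    soft-tailed variant, placing small mass below the bound, is not
    implemented).
    """
    if t_min <= 0 or scale_c <= 0:
        raise ValueError("t_min and scale_c must be positive")
    if offset_p <= 0:
        raise ValueError("offset_p must be positive")
    loc = t_min * (1.0 + offset_p)
    scale = scale_c * t_min
    base = stats.cauchy(loc=loc, scale=scale)
    z = 1.0 - base.cdf(t_min)  # mass of the untruncated Cauchy above t_min

    def pdf(t):
        out = np.where(t >= t_min, base.pdf(t) / z, 0.0)
        return out

    def cdf(t):
        return np.clip((base.cdf(t) - base.cdf(t_min)) / z, 0.0, 1.0)

    def ppf(q):
        return base.ppf(base.cdf(t_min) + np.asarray(q) * z)

    return CalibrationDensity(
        kind="truncated_cauchy",
        params={"t_min": t_min, "offset_p": offset_p, "scale_c": scale_c,
                "mode": loc, "scale": scale},
        node_label=node_label,
        _pdf=pdf,
        _cdf=cdf,
        _ppf=ppf,
    )


def max_bound(t_max: float, node_label: str | None = None) -> CalibrationDensity:
    """Hard maximum age: uniform density on [0, t_max] Myr."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    dist = stats.uniform(loc=0.0, scale=t_max)
    return CalibrationDensity(
        kind="max_bound",
        params={"t_max": t_max},
        node_label=node_label,
        _pdf=dist.pdf,
        _cdf=dist.cdf,
        _ppf=dist.ppf,
    )
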
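"""Fluorescence-titration binding analysis: fraction bound and Hill fits.

A dye-labeled oligo at fixed concentration (100 nM in the assays this
mirrors) is titrated with a nucleolin domain pair; the emission intensity
at 664 nm tracks complex formation.  Intensities are converted to the
fraction bound

    α = (I − I_free) / (I_bound − I_free)

and fit with the Hill saturation model

    α = c^n / (KD + c^n)

where c is the titrant (protein) concentration, n the Hill coefficient
and KD the apparent equilibrium constant.  As written the model's KD has
units molar^n, so alongside it the fit reports KD^(1/n) — the molar
half-saturation concentration — which is the number binding studies
quote; α = 1/2 exactly at c = KD^(1/n).

When the half-saturation concentration is far below the probe
concentration the titration is depletion-limited and the Hill model's KD
is an upper bound rather than a true affinity; such fits carry a
``depletion_flag``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model

from .errors import FitError, InputError

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "fraction_bound",
    "hill",
    "fit_hill",
    "fit_titration",
]

#: relative step between the last two intensities below which the series is
#: considered to have reached its binding plateau
PLATEAU_REL_TOL = 0.05


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: titrant concentrations (M) vs emission intensity."""

    titrant_conc: np.ndarray  # molar, increasing, first point 0
    intensity: np.ndarray
    probe_conc: float = 100e-9  # molar
    i_free: float | None = None  # defaults to intensity at zero titrant
    i_bound: float | None = None  # defaults to the saturation plateau

    def __post_init__(self) -> None:
        c = np.asarray(self.titrant_conc, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise InputError("concentration and intensity must be 1-D, equal length")
        if c[0] != 0.0:
            raise InputError("first titration point must be at zero titrant")
        if np.any(c < 0) or not np.all(np.diff(c) > 0):
            raise InputError("titrant concentrations must be non-negative, increasing")
        object.__setattr__(self, "titrant_conc", c)
        object.__setattr__(self, "intensity", y)
        if self.i_free is None:
            object.__setattr__(self, "i_free", float(y[0]))


@dataclass(frozen=True)
class BindingFit:
    kd: float  # apparent equilibrium constant, units molar^n
    kd_molar_equivalent: float  # kd ** (1/n), molar
    n_hill: float
    rss: float
    converged: bool
    depletion_flag: bool = False


def fraction_bound(series: TitrationSeries) -> np.ndarray:
    """α_i = (I_i − I_free)/(I_bound − I_free).

    ``i_bound`` defaults to the plateau (mean of the final two points);
    if the series shows no plateau and no explicit ``i_bound`` is given
    this is an error.  α values outside [0, 1] (noise at the endpoints)
    are retained.
    """
    y = series.intensity
    i_free = series.i_free
    i_bound = series.i_bound
    if i_bound is None:
        span = abs(y[-1] - y[0])
        if span == 0:
            raise InputError("no transition: intensity is constant")
        # a still-rising (or still-falling) series shows a consistent trend
        # over the last two increments; isolated noisy steps do not
        direction = np.sign(y[-1] - y[0])
        d1 = direction * (y[-2] - y[-3])
        d2 = direction * (y[-1] - y[-2])
        if min(d1, d2) > PLATEAU_REL_TOL * span:
            raise InputError(
                "no saturation plateau detected; supply i_bound explicitly"
            )
        i_bound = float(np.mean(y[-2:]))
    if i_bound == i_free:
        raise InputError("i_bound equals i_free: no dynamic range")
    return (y - i_free) / (i_bound - i_free)


def hill(c, kd, n):
    """Hill saturation: α = c^n / (kd + c^n); kd in molar^n."""
    c = np.asarray(c, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.where(c > 0, c**n / (kd + c**n), 0.0)
    return out


def fit_hill(
    conc: np.ndarray,
    alpha: np.ndarray,
    n_fixed: float | None = None,
    probe_conc: float | None = None,
) -> BindingFit:
    """Least-squares Hill fit of α against titrant concentration (molar).

    ``n_fixed`` pins the Hill coefficient; otherwise n is free within
    (0.1, 10), initialized at 1 with KD0 from the concentration nearest
    α = 0.5.  Raises when the data show no transition inside the
    concentration range.
    """
    conc = np.asarray(conc, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if len(conc) < 6:
        raise InputError("need at least 6 titration points to fit")
    if alpha.max() < 0.2 or alpha.min() > 0.8:
        raise FitError("no transition in range: α never crosses mid-saturation")

    nz = conc[conc > 0]
    kd0 = float(nz[np.argmin(np.abs(alpha[conc > 0] - 0.5))])

    # same model as the Hill form with KD = kd_molar**n, but parameterized
    # by the molar half-saturation constant, which keeps the optimizer on a
    # single well-conditioned scale for any n
    def hill_molar(c, kd_molar, n):
        return hill(c, kd_molar**n, n)

    model = Model(hill_molar)
    params = model.make_params(
        kd_molar=kd0, n=1.0 if n_fixed is None else n_fixed
    )
    params["kd_molar"].set(min=1e-300)
    params["n"].set(min=0.1, max=10.0, vary=n_fixed is None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = model.fit(alpha, params, c=conc)
    kd_molar = float(out.params["kd_molar"].value)
    n = float(out.params["n"].value)
    kd = kd_molar**n
    depleted = probe_conc is not None and kd_molar < probe_conc / 10.0
    return BindingFit(
        kd=kd,
        kd_molar_equivalent=kd_molar,
        n_hill=n,
        rss=float(np.sum(out.residual**2)),
        converged=bool(out.success),
        depletion_flag=bool(depleted),
    )


def fit_titration(
    series: TitrationSeries, n_fixed: float | None = None
) -> tuple[np.ndarray, BindingFit]:
    """Convenience: α transform then Hill fit; returns (α, fit)."""
    alpha = fraction_bound(series)
    fit = fit_hill(
        series.titrant_conc, alpha, n_fixed=n_fixed, probe_conc=series.probe_conc
    )
    return alpha, fit
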
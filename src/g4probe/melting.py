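"""Melting-curve analysis: folded fraction, Boltzmann Tm fits, ΔTm, S factor.

A FRET-melting competition (FRET-MC) plate contains a doubly labeled
quadruplex probe (F21T) alone, with a stabilizing G4 ligand (PhenDC3),
and with ligand plus each competitor oligo.  A competitor that itself
folds into a quadruplex sequesters the ligand and erodes the
ligand-induced melting-temperature shift; the S factor

    S = ΔTm(probe + ligand + competitor) / ΔTm(probe + ligand)

is therefore ~0 for strong quadruplex formers and ~1 for inert oligos.

Melting transitions are fit with a four-parameter Boltzmann sigmoid

    y(T) = A2 + (A1 - A2) / (1 + exp((T - Tm) / dT))

whose inflection is Tm; asymptotes are free so raw fluorescence and
normalized (folded-fraction) curves are both fittable.  CD-melting curves
recorded at 260 nm go through the same machinery after conversion to a
folded fraction θ = (CD - CDmin) / (CDmax - CDmin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lmfit import Model

from .errors import FitError, InputError

__all__ = [
    "Channel",
    "MeltingCurve",
    "FoldedFractionCurve",
    "MeltFit",
    "CompetitionResult",
    "folded_fraction",
    "boltzmann",
    "fit_boltzmann",
    "delta_tm",
    "s_factor",
    "fretmc_summary",
]

#: ligand stabilization below this (°C) means the competition assay has no
#: dynamic range and S is undefined
MIN_REFERENCE_SHIFT = 0.5


class Channel(str, Enum):
    FAM = "FAM"
    CD260 = "CD260"


@dataclass(frozen=True)
class MeltingCurve:
    """A (temperature, signal) melting trace for one well."""

    temperatures: np.ndarray  # °C, strictly increasing
    signal: np.ndarray
    channel: Channel = Channel.FAM
    sample_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise InputError("temperatures and signal must be 1-D, equal length")
        if len(t) < 10:
            raise InputError("melting curve needs at least 10 points")
        if not np.all(np.diff(t) > 0):
            raise InputError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class FoldedFractionCurve:
    temperatures: np.ndarray
    theta: np.ndarray  # in [0, 1], min 0 and max 1 by construction
    cd_min: float
    cd_max: float
    sample_id: str = ""


@dataclass(frozen=True)
class MeltFit:
    tm: float  # °C, sigmoid inflection
    slope: float  # °C, Boltzmann width dT (> 0)
    lower_asymptote: float
    upper_asymptote: float
    rss: float
    converged: bool
    tm_in_range: bool = True
    sample_id: str = ""


@dataclass(frozen=True)
class CompetitionResult:
    competitor: str
    delta_tm_reference: float  # Tm(probe+ligand) - Tm(probe)
    delta_tm_competitor: float  # Tm(probe+ligand+competitor) - Tm(probe)
    s_factor: float


def folded_fraction(
    curve: MeltingCurve, orientation: str = "raw"
) -> FoldedFractionCurve:
    """Min-max normalize a melting trace to a folded fraction θ in [0, 1].

    ``orientation='raw'`` maps the signal minimum to 0 and maximum to 1.
    ``orientation='folded_high'`` additionally flips the curve if needed so
    that the folded (low-temperature) side sits at θ = 1, which is the
    natural reading of a denaturation curve whatever the raw signal
    direction.
    """
    s = curve.signal
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        raise InputError("no transition: signal is constant")
    theta = (s - lo) / (hi - lo)
    if orientation == "folded_high":
        # flip when the low-temperature end is nearer 0 than 1
        k = max(2, len(theta) // 10)
        if theta[:k].mean() < theta[-k:].mean():
            theta = 1.0 - theta
    elif orientation != "raw":
        raise InputError(f"unknown orientation {orientation!r}")
    return FoldedFractionCurve(
        temperatures=curve.temperatures,
        theta=theta,
        cd_min=lo,
        cd_max=hi,
        sample_id=curve.sample_id,
    )


def boltzmann(T, tm, dt, a1, a2):
    """Four-parameter Boltzmann sigmoid; ``a1`` is the low-T asymptote."""
    return a2 + (a1 - a2) / (1.0 + np.exp((T - tm) / dt))


def fit_boltzmann(curve: MeltingCurve | FoldedFractionCurve) -> MeltFit:
    """Least-squares Boltzmann fit; Tm is the inflection temperature.

    Initialization is data-driven: Tm0 at the steepest central-difference
    slope, dT0 = 2 °C, asymptotes from the first/last deciles.  No
    smoothing is applied — least squares already averages the noise.
    """
    t = curve.temperatures
    y = curve.theta if isinstance(curve, FoldedFractionCurve) else curve.signal
    if len(t) < 10:
        raise InputError("need at least 10 points to fit a melting transition")

    dy = np.gradient(y, t)
    tm0 = float(t[np.argmax(np.abs(dy))])
    k = max(2, len(y) // 10)
    a1_0, a2_0 = float(np.mean(y[:k])), float(np.mean(y[-k:]))
    span = abs(a1_0 - a2_0) or 1.0

    model = Model(boltzmann)
    params = model.make_params(tm=tm0, dt=2.0, a1=a1_0, a2=a2_0)
    params["dt"].set(min=1e-3, max=50.0)
    params["tm"].set(min=t[0] - 20.0, max=t[-1] + 20.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = model.fit(y, params, T=t)
        converged = bool(out.success) and abs(out.params["a1"] - out.params["a2"]) > 1e-3 * span
    except Exception:
        return MeltFit(
            tm=float("nan"), slope=float("nan"),
            lower_asymptote=float("nan"), upper_asymptote=float("nan"),
            rss=float("nan"), converged=False,
            sample_id=getattr(curve, "sample_id", ""),
        )
    tm = float(out.params["tm"].value)
    a1, a2 = float(out.params["a1"].value), float(out.params["a2"].value)
    return MeltFit(
        tm=tm,
        slope=float(out.params["dt"].value),
        lower_asymptote=min(a1, a2),
        upper_asymptote=max(a1, a2),
        rss=float(np.sum(out.residual**2)),
        converged=converged,
        tm_in_range=bool(t[0] <= tm <= t[-1]),
        sample_id=getattr(curve, "sample_id", ""),
    )


def delta_tm(fit_a: MeltFit, fit_b: MeltFit) -> float:
    """Tm(a) − Tm(b), in °C; both fits must have converged."""
    if not (fit_a.converged and fit_b.converged):
        raise FitError("delta_tm requires converged fits on both sides")
    return fit_a.tm - fit_b.tm


def s_factor(
    tm_probe: float, tm_probe_ligand: float, tm_probe_ligand_competitor: float,
    competitor: str = "",
) -> CompetitionResult:
    """Competition S factor from three condition-level Tm values."""
    d_ref = tm_probe_ligand - tm_probe
    d_comp = tm_probe_ligand_competitor - tm_probe
    if abs(d_ref) < MIN_REFERENCE_SHIFT:
        raise FitError(
            "ligand stabilization absent: reference ΔTm "
            f"{d_ref:.2f} °C below {MIN_REFERENCE_SHIFT} °C"
        )
    return CompetitionResult(
        competitor=competitor,
        delta_tm_reference=d_ref,
        delta_tm_competitor=d_comp,
        s_factor=d_comp / d_ref,
    )


PROBE_CONDITION = "F21T"
REFERENCE_CONDITION = "F21T+PhenDC3"


def fretmc_summary(
    fits_by_condition: Mapping[str, Sequence[MeltFit]],
    probe_condition: str = PROBE_CONDITION,
    reference_condition: str = REFERENCE_CONDITION,
) -> pd.DataFrame:
    """Per-competitor FRET-MC table from replicate fits.

    Replicate Tm values (one fit per plate) are averaged per condition
    before ΔTm and S are formed.  Conditions other than the probe-alone
    and probe+ligand references are treated as competitors.  Columns:
    competitor, tm_mean, tm_sd, delta_tm, s_factor.
    """
    for cond in (probe_condition, reference_condition):
        if cond not in fits_by_condition:
            raise InputError(f"plate is missing required condition {cond!r}")

    def tm_stats(fits: Sequence[MeltFit]) -> tuple[float, float]:
        tms = [f.tm for f in fits if f.converged]
        if not tms:
            raise FitError("no converged fits for a condition")
        return float(np.mean(tms)), float(np.std(tms, ddof=1)) if len(tms) > 1 else 0.0

    tm_probe, _ = tm_stats(fits_by_condition[probe_condition])
    tm_ref, _ = tm_stats(fits_by_condition[reference_condition])
    rows = []
    for cond, fits in fits_by_condition.items():
        if cond in (probe_condition, reference_condition):
            continue
        tm_mean, tm_sd = tm_stats(fits)
        res = s_factor(tm_probe, tm_ref, tm_mean, competitor=cond)
        rows.append(
            {
                "competitor": cond,
                "tm_mean": tm_mean,
                "tm_sd": tm_sd,
                "delta_tm": res.delta_tm_competitor,
                "s_factor": res.s_factor,
            }
        )
    return pd.DataFrame(
        rows, columns=["competitor", "tm_mean", "tm_sd", "delta_tm", "s_factor"]
    )
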
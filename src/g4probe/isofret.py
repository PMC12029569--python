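"""Isothermal FRET competition (iso-FRET) F values.

At constant temperature a fluorescent strand F22 hybridizes to its
quencher-bearing complement 37Q, quenching its signal, unless a
quadruplex-stabilizing ligand holds F22 folded.  A competitor that forms
a quadruplex sequesters the ligand, lets the duplex form, and lowers the
fluorescence.  The normalized endpoint readout is

    F = (FI_competitor - FI_duplex) / (FI_F22 - FI_duplex)

so F = 1 means full protection of F22 (duplex prevented) and F = 0 means
no protection.  F values are joined with the CF factor so competitors
that could simply hybridize to F22 are flagged as confounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["IsoFretMeasurement", "f_value", "summarize_isofret"]

#: CF above this marks a competitor as potentially hybridizing to the probe
#: directly (artifact default, configurable — not an assay constant).
CF_CONFOUND_THRESHOLD = 0.5


@dataclass(frozen=True)
class IsoFretMeasurement:
    """Endpoint intensities for one competitor replicate and its controls."""

    fi_competitor: float  # competitor + 37Q + ligand + F22
    fi_f22: float  # F22 alone
    fi_duplex: float  # F22 + 37Q duplex
    replicate_id: str = ""
    competitor_id: str = ""

    def __post_init__(self) -> None:
        if min(self.fi_competitor, self.fi_f22, self.fi_duplex) < 0:
            raise InputError("fluorescence intensities must be >= 0")


def f_value(m: IsoFretMeasurement, rel_floor: float = 1e-9) -> float:
    """Eq-style normalized endpoint: (FI_comp − FI_duplex)/(FI_F22 − FI_duplex).

    Not clipped: values slightly outside [0, 1] (noise, gain drift) are
    returned as-is so downstream summaries can see them.
    """
    denom = m.fi_f22 - m.fi_duplex
    if abs(denom) <= rel_floor * max(abs(m.fi_f22), 1.0):
        raise InputError("no dynamic range: FI(F22) equals FI(duplex)")
    return (m.fi_competitor - m.fi_duplex) / denom


def summarize_isofret(
    measurements: Mapping[str, Sequence[IsoFretMeasurement]],
    cf_factors: Mapping[str, float] | None = None,
    cf_threshold: float = CF_CONFOUND_THRESHOLD,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-competitor F-value summary with CF annotation.

    By default F is computed per replicate and then averaged (plate gain
    drifts between wells); ``pooled=True`` instead computes a single F
    from replicate-mean intensities.  Competitors whose CF factor exceeds
    ``cf_threshold`` are flagged as potentially confounded by direct
    hybridization; a missing CF leaves the flag unset (NaN CF).
    """
    cf_factors = cf_factors or {}
    rows = []
    for comp, reps in measurements.items():
        if not reps:
            raise InputError(f"competitor {comp!r} has no replicates")
        if pooled:
            mean_m = IsoFretMeasurement(
                fi_competitor=float(np.mean([m.fi_competitor for m in reps])),
                fi_f22=float(np.mean([m.fi_f22 for m in reps])),
                fi_duplex=float(np.mean([m.fi_duplex for m in reps])),
                competitor_id=comp,
            )
            f_mean, f_sd = f_value(mean_m), float("nan")
        else:
            fs = [f_value(m) for m in reps]
            f_mean = float(np.mean(fs))
            f_sd = float(np.std(fs, ddof=1)) if len(fs) > 1 else 0.0
        cf = cf_factors.get(comp, float("nan"))
        rows.append(
            {
                "competitor": comp,
                "f_mean": f_mean,
                "f_sd": f_sd,
                "n_replicates": len(reps),
                "cf": cf,
                "hybridization_confound": bool(cf > cf_threshold)
                if not np.isnan(cf)
                else False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "competitor", "f_mean", "f_sd", "n_replicates", "cf",
            "hybridization_confound",
        ],
    )
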
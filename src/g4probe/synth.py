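"""Synthetic plate-reader curves, spectra, titrations and sequence sets.

Every input the analysis modules consume can be generated here with known
ground truth, a stated Gaussian noise model, and a seed that fully
determines the output — so parameter-recovery tests and the end-to-end
pipeline run without wet-lab data.

The defaults mirror the assay conditions the pipeline was built around:

* melting plates: 20-95 °C in 0.5 °C steps, Boltzmann transitions with
  width 3 °C, three replicate plates, noise sd 0.005 of the amplitude;
* titrations: 100 nM probe, titrant from 0 to 150 nM over 16 points,
  1% multiplicative noise.  The nonzero points are geometric (0.5 -> 150
  nM, ~1.5x steps): stepwise sub-equivalent additions are how a titration
  against a 100 nM probe resolves a low-nanomolar KD, which a 10 nM
  linear step cannot;
* difference-spectrum pairs: a smooth absorbance envelope for both
  states plus three signed Gaussian bands at 245/273/295 nm in the
  folded state (folded − unfolded convention: 245 and 273 negative,
  295 positive);
* sequence sets: the AS1411 derivative family plus composition-matched
  shuffled decoys.

Each generator returns in-memory objects together with a ``truth`` dict
recording every parameter and the noise model, ready to be serialized
next to the generated files.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .isofret import IsoFretMeasurement
from .melting import Channel, MeltingCurve, boltzmann
from .sequences import OligoSequence, as1411_family
from .spectra import FoldState, Spectrum

__all__ = [
    "default_melting_grid",
    "default_titration_grid",
    "gen_melting_plate",
    "gen_titration",
    "gen_spectrum_pair",
    "gen_isofret_plate",
    "gen_sequence_set",
]


def default_melting_grid() -> np.ndarray:
    """Temperatures 20-95 °C in 0.5 °C steps (151 points)."""
    return np.arange(20.0, 95.0 + 0.25, 0.5)


def default_titration_grid() -> np.ndarray:
    """Titrant grid 0-150 nM, 16 points: zero plus 15 geometric 0.5-150 nM."""
    return np.concatenate([[0.0], np.geomspace(0.5e-9, 150e-9, 15)])


def gen_melting_plate(
    tm_by_condition: Mapping[str, float],
    dt: float = 3.0,
    amplitude: float = 1.0,
    baseline: float = 0.1,
    noise_sd: float = 0.005,
    grid: np.ndarray | None = None,
    n_plates: int = 3,
    seed: int = 0,
) -> tuple[list[MeltingCurve], dict]:
    """Boltzmann melting curves for each condition on each replicate plate.

    ``noise_sd`` is in units of the transition amplitude.  The FAM signal
    rises on melting (quencher separates), so the low-temperature
    asymptote is ``baseline`` and the high-temperature one
    ``baseline + amplitude``.
    """
    grid = default_melting_grid() if grid is None else np.asarray(grid, float)
    for cond, tm in tm_by_condition.items():
        if not grid[0] <= tm <= grid[-1]:
            raise InputError(
                f"truth Tm {tm} °C for {cond!r} outside grid "
                f"[{grid[0]}, {grid[-1]}]"
            )
    rng = np.random.default_rng(seed)
    curves = []
    for plate in range(1, n_plates + 1):
        for cond, tm in tm_by_condition.items():
            # rising sigmoid: a1 (low-T) = baseline, a2 = baseline + amplitude
            y = boltzmann(grid, tm, dt, baseline, baseline + amplitude)
            y = y + rng.normal(0.0, noise_sd * amplitude, grid.shape)
            curves.append(
                MeltingCurve(
                    temperatures=grid,
                    signal=y,
                    channel=Channel.FAM,
                    sample_id=f"{cond}|plate{plate}",
                )
            )
    truth = {
        "kind": "melting_plate",
        "tm_by_condition": dict(tm_by_condition),
        "dt": dt,
        "amplitude": amplitude,
        "baseline": baseline,
        "noise": {"distribution": "gaussian", "sd_of_amplitude": noise_sd},
        "grid": {"start": float(grid[0]), "stop": float(grid[-1]),
                 "n": int(len(grid))},
        "n_plates": n_plates,
        "seed": seed,
    }
    return curves, truth


def gen_titration(
    kd_molar: float,
    n_hill: float = 1.5,
    i_free: float = 1.0,
    i_bound: float = 5.0,
    probe_conc: float = 100e-9,
    grid: np.ndarray | None = None,
    noise_rel: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """One Hill-model titration with multiplicative Gaussian noise.

    ``kd_molar`` is the molar half-saturation concentration; the Hill-form
    constant used to synthesize is kd_molar**n_hill.  Returns a DataFrame
    (titrant_conc_molar, intensity) and the truth record; if the grid's
    nonzero points do not bracket kd_molar the truth record carries a
    ``grid_warning`` (the KD is then unidentifiable from this series).
    """
    grid = default_titration_grid() if grid is None else np.asarray(grid, float)
    rng = np.random.default_rng(seed)
    kd_eq = kd_molar**n_hill
    c = grid
    with np.errstate(invalid="ignore"):
        alpha = np.where(c > 0, c**n_hill / (kd_eq + c**n_hill), 0.0)
    intensity = i_free + (i_bound - i_free) * alpha
    intensity = intensity * (1.0 + rng.normal(0.0, noise_rel, c.shape))
    df = pd.DataFrame({"titrant_conc_molar": c, "intensity": intensity})
    nz = c[c > 0]
    warning = None
    if len(nz) == 0 or not (nz.min() <= kd_molar <= nz.max()):
        warning = "grid does not span the half-saturation concentration"
    truth = {
        "kind": "titration",
        "kd_molar": kd_molar,
        "n_hill": n_hill,
        "i_free": i_free,
        "i_bound": i_bound,
        "probe_conc_molar": probe_conc,
        "noise": {"distribution": "gaussian", "relative_sd": noise_rel},
        "grid": [float(x) for x in c],
        "seed": seed,
    }
    if warning:
        truth["grid_warning"] = warning
    return df, truth


#: folded − unfolded band amplitudes of the default synthetic G4 signature,
#: in absorbance units on a ~0.8 OD envelope
DEFAULT_G4_BANDS = ((245.0, -0.04), (273.0, -0.10), (295.0, +0.05))


def gen_spectrum_pair(
    bands: Sequence[tuple[float, float]] = DEFAULT_G4_BANDS,
    band_width_nm: float = 9.0,
    envelope_amp: float = 0.8,
    noise_sd: float = 0.002,
    grid: np.ndarray | None = None,
    dilution_factor: float = 1.0,
    seed: int = 0,
) -> tuple[Spectrum, Spectrum, dict]:
    """A (folded, unfolded) absorbance spectrum pair with known bands.

    The unfolded state is a smooth DNA absorbance envelope (Gaussian hump
    centered at 258 nm); the folded state adds signed Gaussian difference
    bands.  ``bands`` are (center nm, folded − unfolded amplitude).
    """
    grid = np.arange(220.0, 320.0 + 0.25, 0.5) if grid is None else np.asarray(grid, float)
    for center, _ in bands:
        if not grid[0] <= center <= grid[-1]:
            raise InputError(f"band center {center} nm outside wavelength grid")
    rng = np.random.default_rng(seed)
    envelope = envelope_amp * np.exp(-(((grid - 258.0) / 28.0) ** 2))
    folded = envelope.copy()
    for center, amp in bands:
        folded += amp * np.exp(-(((grid - center) / band_width_nm) ** 2))
    unfolded_noisy = envelope + rng.normal(0.0, noise_sd, grid.shape)
    folded_noisy = folded + rng.normal(0.0, noise_sd, grid.shape)
    # a diluted measurement reads lower by the dilution factor
    unfolded_noisy = unfolded_noisy / dilution_factor
    truth = {
        "kind": "spectrum_pair",
        "bands": [{"center_nm": c, "amplitude": a} for c, a in bands],
        "band_width_nm": band_width_nm,
        "envelope_amp": envelope_amp,
        "noise": {"distribution": "gaussian", "sd": noise_sd},
        "dilution_factor": dilution_factor,
        "grid": {"start": float(grid[0]), "stop": float(grid[-1]),
                 "n": int(len(grid))},
        "seed": seed,
    }
    return (
        Spectrum(grid, folded_noisy, state=FoldState.FOLDED),
        Spectrum(grid, unfolded_noisy, state=FoldState.UNFOLDED,
                 dilution_factor=dilution_factor),
        truth,
    )


def gen_isofret_plate(
    f_by_competitor: Mapping[str, float],
    fi_f22: float = 100.0,
    fi_duplex: float = 10.0,
    noise_rel: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[dict[str, list[IsoFretMeasurement]], dict]:
    """Endpoint intensities realizing a target F value per competitor."""
    rng = np.random.default_rng(seed)
    out: dict[str, list[IsoFretMeasurement]] = {}
    for comp, f_true in f_by_competitor.items():
        reps = []
        for r in range(1, n_replicates + 1):
            fi_c = fi_duplex + f_true * (fi_f22 - fi_duplex)
            noisy = np.array([fi_c, fi_f22, fi_duplex])
            noisy = noisy * (1.0 + rng.normal(0.0, noise_rel, 3))
            reps.append(
                IsoFretMeasurement(
                    fi_competitor=float(noisy[0]),
                    fi_f22=float(noisy[1]),
                    fi_duplex=float(noisy[2]),
                    replicate_id=f"rep{r}",
                    competitor_id=comp,
                )
            )
        out[comp] = reps
    truth = {
        "kind": "isofret_plate",
        "f_by_competitor": dict(f_by_competitor),
        "fi_f22": fi_f22,
        "fi_duplex": fi_duplex,
        "noise": {"distribution": "gaussian", "relative_sd": noise_rel},
        "n_replicates": n_replicates,
        "seed": seed,
    }
    return out, truth


def gen_sequence_set(
    n_decoys: int = 3, seed: int = 0
) -> tuple[list[OligoSequence], dict]:
    """The AS1411 derivative family plus composition-matched shuffled decoys.

    Decoys are per-sequence shuffles of family members (same length and
    base composition) and carry ids ``decoy<k>``.
    """
    rng = np.random.default_rng(seed)
    family = as1411_family()
    seqs = list(family)
    for k in range(1, n_decoys + 1):
        template = family[(k - 1) % len(family)]
        letters = np.array(list(template.bases))
        rng.shuffle(letters)
        seqs.append(
            OligoSequence(id=f"decoy{k}", bases="".join(letters))
        )
    truth = {
        "kind": "sequence_set",
        "family": [s.id for s in family],
        "n_decoys": n_decoys,
        "seed": seed,
    }
    return seqs, truth
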
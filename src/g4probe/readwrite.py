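"""Readers and writers for the pipeline's plain-text formats.

Formats:

* FASTA for oligo sets (via Biopython SeqIO).
* Melting plate CSV, two dialects auto-detected by header:
  long (``well,sample_id,condition,temperature,signal``) and wide
  (first column ``temperature``, one column per well).
* Iso-FRET endpoint CSV: ``well,competitor_id,condition,intensity`` with
  condition in {competitor, f22_alone, duplex}.
* Spectrum / titration CSVs: a data table preceded by ``# key: value``
  metadata lines (state and dilution for spectra; probe concentration and
  emission wavelength for titrations).
* Reports: TSV with stable column order and 6-significant-digit floats,
  or versioned JSON.

Readers attach units and report malformed rows with line numbers; ragged
or truncated tables are rejected rather than silently repaired.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import TitrationSeries
from .errors import InputError
from .isofret import IsoFretMeasurement
from .melting import Channel, MeltingCurve
from .sequences import OligoSequence
from .spectra import FoldState, Spectrum

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_melting_csv",
    "write_melting_csv",
    "melting_curves_by_condition",
    "read_isofret_csv",
    "write_isofret_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_titration_csv",
    "write_titration_csv",
    "write_report",
]

REPORT_SCHEMA_VERSION = 1

_LONG_COLUMNS = ["well", "sample_id", "condition", "temperature", "signal"]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[OligoSequence]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seqs.append(OligoSequence(id=rec.id, bases=str(rec.seq)))
        except InputError as e:
            raise InputError(f"{path}:{rec.id}: {e}") from e
    if not seqs:
        raise InputError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Iterable[OligoSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------- plate CSV

def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        return pd.read_csv(path, **kw)
    except Exception as e:
        raise InputError(f"{path}: cannot parse CSV: {e}") from e


def read_melting_csv(path: str | Path) -> pd.DataFrame:
    """Read a melting plate CSV in either dialect; return long format.

    Long format is recognized by the presence of ``temperature`` and
    ``signal`` columns; otherwise a first column named like temperature
    followed by one column per well is treated as the wide dialect.
    """
    df = _read_csv(path)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if {"temperature", "signal"}.issubset(cols):
        missing = [c for c in _LONG_COLUMNS if c not in cols]
        if missing:
            raise InputError(f"{path}: long dialect missing columns {missing}")
        out = df[_LONG_COLUMNS].copy()
    elif cols and cols[0].lower() in ("temperature", "temperature_c", "temp"):
        if len(cols) < 2:
            raise InputError(f"{path}: wide dialect has no well columns")
        out = df.melt(
            id_vars=[cols[0]], var_name="well", value_name="signal"
        ).rename(columns={cols[0]: "temperature"})
        out["sample_id"] = out["well"]
        out["condition"] = out["well"]
        out = out[_LONG_COLUMNS]
    else:
        raise InputError(
            f"{path}: unknown dialect; expected long columns "
            f"{_LONG_COLUMNS} or a wide table starting with 'temperature'"
        )
    for col in ("temperature", "signal"):
        bad = out[pd.to_numeric(out[col], errors="coerce").isna()]
        if len(bad):
            lines = (bad.index + 2).tolist()[:5]
            raise InputError(
                f"{path}: non-numeric {col!r} at line(s) {lines}"
            )
        out[col] = out[col].astype(float)
    counts = out.groupby("well", sort=False).size()
    if counts.nunique() > 1:
        raise InputError(
            f"{path}: wells have unequal row counts {dict(counts)} "
            "(truncated file?)"
        )
    return out.reset_index(drop=True)


def melting_curves_by_condition(
    df: pd.DataFrame, channel: Channel = Channel.FAM
) -> dict[str, list[MeltingCurve]]:
    """Group a long-format plate table into per-condition curve lists."""
    out: dict[str, list[MeltingCurve]] = {}
    for (cond, well), grp in df.groupby(["condition", "well"], sort=False):
        grp = grp.sort_values("temperature")
        curve = MeltingCurve(
            temperatures=grp["temperature"].to_numpy(),
            signal=grp["signal"].to_numpy(),
            channel=channel,
            sample_id=str(well),
        )
        out.setdefault(str(cond), []).append(curve)
    return out


def write_melting_csv(
    curves: Sequence[MeltingCurve], path: str | Path, dialect: str = "long"
) -> None:
    """Write curves in the long dialect (condition parsed from sample_id
    as the part before '|', the full sample_id serving as the well)."""
    if dialect != "long":
        raise InputError(f"unsupported write dialect {dialect!r}")
    rows = []
    for c in curves:
        condition = c.sample_id.split("|", 1)[0] if c.sample_id else ""
        for t, s in zip(c.temperatures, c.signal):
            rows.append(
                {
                    "well": c.sample_id,
                    "sample_id": c.sample_id,
                    "condition": condition,
                    "temperature": t,
                    "signal": s,
                }
            )
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(
        path, index=False, float_format="%.6g"
    )


# ---------------------------------------------------------- isofret CSV

_ISOFRET_COLUMNS = ["well", "competitor_id", "condition", "intensity"]
_ISOFRET_CONDITIONS = {"competitor", "f22_alone", "duplex"}


def read_isofret_csv(path: str | Path) -> dict[str, list[IsoFretMeasurement]]:
    """Endpoint plate -> per-competitor measurements.

    Control wells (``f22_alone``, ``duplex``) are averaged over the plate
    and shared by every competitor well.
    """
    df = _read_csv(path)
    missing = [c for c in _ISOFRET_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    unknown = set(df["condition"]) - _ISOFRET_CONDITIONS
    if unknown:
        raise InputError(
            f"{path}: unknown condition(s) {sorted(unknown)}; "
            f"expected {sorted(_ISOFRET_CONDITIONS)}"
        )
    bad = df[pd.to_numeric(df["intensity"], errors="coerce").isna()]
    if len(bad):
        raise InputError(
            f"{path}: non-numeric intensity at line(s) {(bad.index + 2).tolist()[:5]}"
        )
    df["intensity"] = df["intensity"].astype(float)
    controls = df[df["condition"] != "competitor"]
    for cond in ("f22_alone", "duplex"):
        if not (controls["condition"] == cond).any():
            raise InputError(f"{path}: no {cond!r} control wells")
    fi_f22 = float(controls.loc[controls["condition"] == "f22_alone", "intensity"].mean())
    fi_duplex = float(controls.loc[controls["condition"] == "duplex", "intensity"].mean())
    out: dict[str, list[IsoFretMeasurement]] = {}
    comp = df[df["condition"] == "competitor"]
    for _, row in comp.iterrows():
        m = IsoFretMeasurement(
            fi_competitor=float(row["intensity"]),
            fi_f22=fi_f22,
            fi_duplex=fi_duplex,
            replicate_id=str(row["well"]),
            competitor_id=str(row["competitor_id"]),
        )
        out.setdefault(m.competitor_id, []).append(m)
    if not out:
        raise InputError(f"{path}: no competitor wells")
    return out


def write_isofret_csv(
    measurements: Mapping[str, Sequence[IsoFretMeasurement]], path: str | Path
) -> None:
    rows = []
    well = 0
    for comp, reps in measurements.items():
        for m in reps:
            well += 1
            rows.append(
                {"well": f"W{well}", "competitor_id": comp,
                 "condition": "competitor", "intensity": m.fi_competitor}
            )
    # one control pair per plate, averaged over what the measurements carry
    all_m = [m for reps in measurements.values() for m in reps]
    rows.append({"well": "C1", "competitor_id": "", "condition": "f22_alone",
                 "intensity": float(np.mean([m.fi_f22 for m in all_m]))})
    rows.append({"well": "C2", "competitor_id": "", "condition": "duplex",
                 "intensity": float(np.mean([m.fi_duplex for m in all_m]))})
    pd.DataFrame(rows, columns=_ISOFRET_COLUMNS).to_csv(
        path, index=False, float_format="%.6g"
    )


# -------------------------------------------- metadata-prefixed tables

def _read_with_metadata(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                break
    df = _read_csv(path, skiprows=skip)
    return meta, df


def read_spectrum_csv(path: str | Path) -> Spectrum:
    meta, df = _read_with_metadata(path)
    for col in ("wavelength_nm", "signal"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    state = FoldState(meta.get("state", "folded"))
    dilution = float(meta.get("dilution", 1.0))
    return Spectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        state=state,
        dilution_factor=dilution,
    )


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# state: {spectrum.state.value}\n")
        fh.write(f"# dilution: {spectrum.dilution_factor:g}\n")
        fh.write("wavelength_nm,signal\n")
        for w, s in zip(spectrum.wavelengths, spectrum.signal):
            fh.write(f"{w:.6g},{s:.6g}\n")


def read_titration_csv(path: str | Path) -> TitrationSeries:
    meta, df = _read_with_metadata(path)
    for col in ("titrant_conc_molar", "intensity"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return TitrationSeries(
        titrant_conc=df["titrant_conc_molar"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
        probe_conc=float(meta.get("probe_conc_molar", 100e-9)),
    )


def write_titration_csv(
    df: pd.DataFrame,
    path: str | Path,
    probe_conc: float = 100e-9,
    emission_nm: float = 664.0,
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# probe_conc_molar: {probe_conc:g}\n")
        fh.write(f"# emission_nm: {emission_nm:g}\n")
        fh.write("titrant_conc_molar,intensity\n")
        for c, i in zip(df["titrant_conc_molar"], df["intensity"]):
            fh.write(f"{c:.6g},{i:.6g}\n")


# ---------------------------------------------------------------- reports

def _round_sig(x, sig: int = 6):
    if isinstance(x, (float, np.floating)):
        return float(f"{x:.{sig}g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def write_report(df: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    """Write an analysis table as TSV (6 sig. digits) or versioned JSON."""
    path = Path(path)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif fmt == "json":
        rows = [
            {k: _round_sig(v) for k, v in rec.items()}
            for rec in df.to_dict(orient="records")
        ]
        payload = {"schema_version": REPORT_SCHEMA_VERSION, "rows": rows}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise InputError(f"unknown report format {fmt!r}")
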
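"""Declarative end-to-end runs: generate synthetic inputs, analyze, report.

A run is described by a single YAML config (seed, per-assay truth
parameters); the pipeline generates every input with the synthetic module,
writes it under ``<out>/inputs/``, re-reads it through the normal file
readers, runs the analysis modules, and writes reports under
``<out>/reports/`` together with the config actually used and a manifest
of output hashes.  Outputs contain no timestamps, so two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import align, binding, g4hunter, isofret, melting, readwrite, spectra, synth
from .errors import InputError

__all__ = ["RunConfig", "run_all", "SYNTHETIC_F22"]

log = logging.getLogger("g4probe")

#: Synthetic stand-in for the F22 FRET probe (a telomere-derived 22-mer);
#: real analyses should supply the actual probe sequence via the config.
SYNTHETIC_F22 = "AGGGTTAGGGTTAGGGTTAGGG"

_KNOWN_KEYS = {
    "seed", "probe_sequence", "sequences", "fretmc", "isofret",
    "spectra", "titration",
}


@dataclass(frozen=True)
class RunConfig:
    seed: int
    probe_sequence: str = SYNTHETIC_F22
    sequences: dict = field(default_factory=dict)
    fretmc: dict = field(default_factory=dict)
    isofret: dict = field(default_factory=dict)
    spectra: dict = field(default_factory=dict)
    titration: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in data:
            raise InputError("config must set a seed")
        return cls(**{k: data[k] for k in data})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such config file: {path}")
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, path: Path) -> None:
    log.info("%s -> %s sha256=%s", name, path.name, _sha256(path)[:12])


def run_all(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute every stage; returns a name -> path map of the outputs."""
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    reports = outdir / "reports"
    inputs.mkdir(parents=True, exist_ok=True)
    reports.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 5)
    outputs: dict[str, Path] = {}

    # ------------------------------------------------ sequences + scores
    seq_cfg = dict(config.sequences)
    seqs, seq_truth = synth.gen_sequence_set(
        n_decoys=int(seq_cfg.get("n_decoys", 3)), seed=seeds[0]
    )
    fasta = inputs / "sequences.fasta"
    readwrite.write_fasta(seqs, fasta)
    _stage("sequences", fasta)
    loaded = readwrite.read_fasta(fasta)
    rows = []
    for s in loaded:
        res = g4hunter.g4hunter_score(s)
        cf = align.cf_factor(s, config.probe_sequence)
        rows.append(
            {"id": s.id, "length": len(s), "g4hunter": res.mean_score,
             "cf": cf.cf_factor}
        )
    seq_report = reports / "sequences.tsv"
    readwrite.write_report(pd.DataFrame(rows), seq_report)
    outputs["sequences"] = seq_report
    _stage("g4hunter+cf", seq_report)

    # --------------------------------------------------------- FRET-MC
    fret_cfg = dict(config.fretmc)
    tm_by_condition = fret_cfg.pop("tm_by_condition", None)
    if tm_by_condition is None:
        tm_by_condition = {
            "F21T": 44.0, "F21T+PhenDC3": 61.0,
            "AT14": 46.0, "AT14T": 57.0,
        }
    curves, _ = synth.gen_melting_plate(
        tm_by_condition, seed=seeds[1], **fret_cfg
    )
    plate_csv = inputs / "melting_plate.csv"
    readwrite.write_melting_csv(curves, plate_csv)
    _stage("melting plate", plate_csv)
    df = readwrite.read_melting_csv(plate_csv)
    by_cond = readwrite.melting_curves_by_condition(df)
    fits = {
        cond: [melting.fit_boltzmann(c) for c in cs]
        for cond, cs in by_cond.items()
    }
    fret_report = reports / "fretmc.tsv"
    readwrite.write_report(melting.fretmc_summary(fits), fret_report)
    outputs["fretmc"] = fret_report
    _stage("fretmc", fret_report)

    # --------------------------------------------------------- iso-FRET
    iso_cfg = dict(config.isofret)
    f_by_comp = iso_cfg.pop(
        "f_by_competitor", {"AT14": 0.15, "AT14T": 0.25, "decoy1": 0.95}
    )
    msrmts, _ = synth.gen_isofret_plate(f_by_comp, seed=seeds[2], **iso_cfg)
    iso_csv = inputs / "isofret_plate.csv"
    readwrite.write_isofret_csv(msrmts, iso_csv)
    _stage("isofret plate", iso_csv)
    loaded_m = readwrite.read_isofret_csv(iso_csv)
    cf_map = {
        s.id: align.cf_factor(s, config.probe_sequence).cf_factor
        for s in loaded
        if s.id in loaded_m
    }
    iso_report = reports / "isofret.tsv"
    readwrite.write_report(
        isofret.summarize_isofret(loaded_m, cf_factors=cf_map), iso_report
    )
    outputs["isofret"] = iso_report
    _stage("isofret", iso_report)

    # ----------------------------------------------------------- spectra
    spec_cfg = dict(config.spectra)
    folded, unfolded, _ = synth.gen_spectrum_pair(seed=seeds[3], **spec_cfg)
    f_csv, u_csv = inputs / "spectrum_folded.csv", inputs / "spectrum_unfolded.csv"
    readwrite.write_spectrum_csv(folded, f_csv)
    readwrite.write_spectrum_csv(unfolded, u_csv)
    _stage("spectra", f_csv)
    d = spectra.difference_spectrum(
        readwrite.read_spectrum_csv(f_csv), readwrite.read_spectrum_csv(u_csv)
    )
    diff_csv = reports / "difference_spectrum.csv"
    with open(diff_csv, "w") as fh:
        fh.write("wavelength_nm,delta\n")
        for w, dv in zip(d.wavelengths, d.delta):
            fh.write(f"{w:.6g},{dv:.6g}\n")
    ok, bands, reason = spectra.detect_g4_signature(d)
    bands_json = reports / "bands.json"
    bands_json.write_text(
        json.dumps(
            {
                "schema_version": readwrite.REPORT_SCHEMA_VERSION,
                "is_g4_signature": ok,
                "reason": reason,
                "bands": [
                    {"center_nm": b.center_nm, "sign": b.sign,
                     "prominence": float(f"{b.prominence:.6g}")}
                    for b in bands
                ],
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    outputs["difference_spectrum"] = diff_csv
    outputs["bands"] = bands_json
    _stage("difference spectrum", bands_json)

    # --------------------------------------------------------- titration
    tit_cfg = dict(config.titration)
    kd_molar = float(tit_cfg.pop("kd_molar", 4.6e-9))
    tit_df, _ = synth.gen_titration(kd_molar, seed=seeds[4], **tit_cfg)
    tit_csv = inputs / "titration.csv"
    probe_conc = float(tit_cfg.get("probe_conc", 100e-9))
    readwrite.write_titration_csv(tit_df, tit_csv, probe_conc=probe_conc)
    _stage("titration", tit_csv)
    series = readwrite.read_titration_csv(tit_csv)
    alpha, fit = binding.fit_titration(series)
    alpha_tsv = reports / "alpha.tsv"
    readwrite.write_report(
        pd.DataFrame(
            {"titrant_conc_molar": series.titrant_conc, "alpha": alpha}
        ),
        alpha_tsv,
    )
    fit_json = reports / "binding.json"
    fit_json.write_text(
        json.dumps(
            {
                "schema_version": readwrite.REPORT_SCHEMA_VERSION,
                "kd": float(f"{fit.kd:.6g}"),
                "kd_molar_equivalent": float(f"{fit.kd_molar_equivalent:.6g}"),
                "n_hill": float(f"{fit.n_hill:.6g}"),
                "rss": float(f"{fit.rss:.6g}"),
                "converged": fit.converged,
                "depletion_flag": fit.depletion_flag,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    outputs["alpha"] = alpha_tsv
    outputs["binding"] = fit_json
    _stage("binding", fit_json)

    # ------------------------------------------------- audit trail
    cfg_path = outdir / "config_used.yaml"
    cfg_path.write_text(
        yaml.safe_dump(
            {
                "seed": config.seed,
                "probe_sequence": config.probe_sequence,
                "sequences": config.sequences,
                "fretmc": config.fretmc,
                "isofret": config.isofret,
                "spectra": config.spectra,
                "titration": config.titration,
            },
            sort_keys=True,
        )
    )
    manifest = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return outputs
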
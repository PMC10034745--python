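"""Readers and writers: state-data CSV, peptide lists, FASTA, configs.

The state-data CSV follows the DynamX export convention (columns Protein,
Sequence, Start, End, State, Exposure, Uptake, plus optional Replicate and
Uptake SD).  Exposures are canonically seconds; vendor exports in minutes
are converted with ``exposure_units="min"``.  Parsing is locale-independent
(decimal point only) and row-level failures are reported as diagnostics
without aborting the read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fluidics import InstrumentConfig
from .peptides import PeptideSpec
from .series import UptakeSeries

REQUIRED_COLUMNS = ("Sequence", "Start", "End", "Exposure", "Uptake")


@dataclass(frozen=True)
class RowDiagnostic:
    row: int
    message: str


def read_state_csv(
    path, exposure_units: str = "s", maxd_state: str | None = "maxD"
) -> tuple[list[UptakeSeries], list[RowDiagnostic]]:
    """Read a state-data CSV into one UptakeSeries per (peptide, state).

    Returns the series list and per-row diagnostics for rows that could not
    be parsed (those rows are skipped; valid rows are kept).  A series whose
    ``State`` equals ``maxd_state`` is flagged as a maxD reference.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"state CSV missing required column(s): {', '.join(missing)}")
    if "Protein" not in df.columns:
        df["Protein"] = "peptide"
    if "State" not in df.columns:
        df["State"] = "labeled"

    scale = 60.0 if exposure_units == "min" else 1.0
    if exposure_units not in ("s", "min"):
        raise ValueError("exposure_units must be 's' or 'min'")

    diagnostics: list[RowDiagnostic] = []
    rows = []
    for idx, row in df.iterrows():
        try:
            exposure = float(row["Exposure"]) * scale
            uptake = float(row["Uptake"])
            start = int(float(row["Start"]))
            end = int(float(row["End"]))
        except ValueError as exc:
            diagnostics.append(RowDiagnostic(int(idx) + 2, f"unparseable cell: {exc}"))
            continue
        if exposure <= 0:
            diagnostics.append(
                RowDiagnostic(int(idx) + 2, f"non-positive exposure {exposure}")
            )
            continue
        if uptake < 0:
            diagnostics.append(RowDiagnostic(int(idx) + 2, f"negative uptake {uptake}"))
            continue
        rows.append(
            {
                "Protein": row["Protein"],
                "Sequence": row["Sequence"],
                "Start": start,
                "End": end,
                "State": row["State"],
                "Exposure": exposure,
                "Uptake": uptake,
            }
        )
    series: list[UptakeSeries] = []
    if not rows:
        return series, diagnostics
    clean = pd.DataFrame(rows)
    for (protein, seq, start, end, state), grp in clean.groupby(
        ["Protein", "Sequence", "Start", "End", "State"], sort=True
    ):
        try:
            pep = PeptideSpec(seq, start_residue=int(start), end_residue=int(end))
        except ValueError as exc:
            diagnostics.append(RowDiagnostic(-1, f"peptide {seq!r}: {exc}"))
            continue
        exposures = np.sort(grp["Exposure"].unique())
        reps = int(grp.groupby("Exposure").size().max())
        uptake = np.full((exposures.size, reps), np.nan)
        for i, t in enumerate(exposures):
            vals = grp.loc[grp["Exposure"] == t, "Uptake"].to_numpy(float)
            uptake[i, : vals.size] = vals
        series.append(
            UptakeSeries(
                pep,
                exposures,
                uptake,
                units="Da",
                is_maxD_reference=(maxd_state is not None and state == maxd_state),
                state=str(state),
                protein=str(protein),
            )
        )
    return series, diagnostics


def write_state_csv(series_list: list[UptakeSeries], path) -> None:
    """Write series to a state-data CSV (one row per replicate, seconds)."""
    frames = [s.to_frame() for s in series_list]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.to_csv(path, index=False)


def read_peptide_list_csv(path) -> list[PeptideSpec]:
    """Peptide list with columns sequence[,start,end] (case-insensitive)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sequence" not in df.columns:
        raise ValueError("peptide list CSV missing required column: sequence")
    peptides = []
    for _, row in df.iterrows():
        start = int(row["start"]) if "start" in df.columns else 1
        end = int(row["end"]) if "end" in df.columns else 0
        peptides.append(PeptideSpec(str(row["sequence"]), start, end))
    return peptides


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id (plain parser; uppercased)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def load_instrument_config(path) -> InstrumentConfig:
    """Instrument geometry/limits from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"instrument config {path} did not parse to a mapping")
    if "loop_volumes" in data:
        data["loop_volumes"] = tuple(float(v) for v in data["loop_volumes"])
    return InstrumentConfig(**data)


def dump_instrument_config(cfg: InstrumentConfig, path) -> None:
    data = {
        "tubing_diameter": cfg.tubing_diameter,
        "kinematic_viscosity": cfg.kinematic_viscosity,
        "loop_volumes": list(cfg.loop_volumes),
        "max_flow": cfg.max_flow,
        "min_flow": cfg.min_flow,
        "label_mix_ratio": cfg.label_mix_ratio,
        "quench_mix_ratio": cfg.quench_mix_ratio,
        "stopflow_label_flow": cfg.stopflow_label_flow,
        "stopflow_quench_flow": cfg.stopflow_quench_flow,
        "sample_volume": cfg.sample_volume,
        "dead_volume": cfg.dead_volume,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
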
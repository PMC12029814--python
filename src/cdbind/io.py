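"""CSV/JSON readers and writers shared by all analysis stages.

Shift-table dialect (UTF-8, '.' decimal separator, header required):
    sample_id, A_total_mM, B_total_mM, proton_id, molecule,
    delta_obs_ppm, delta_free_ppm

Thermogram dialect:
    injection_index, volume_uL, heat, heat_units   (heat_units: ucal | uJ)

ITC design JSON: cell_volume_mL, cell_conc_mM, syringe_conc_mM,
temperature_C (injection volumes come from the thermogram CSV).

Concentrations are converted to mol/L and heats to cal on read; the shift
perturbation ddelta = delta_free - delta_obs is computed on load.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .binding_core import ProtonAssignment, ShiftRecord
from .itc import ITCDesign, Thermogram
from .nmr import CVDesign, ShiftTable

__all__ = [
    "read_shift_table",
    "write_shift_table",
    "read_thermogram",
    "write_thermogram",
    "read_itc_design",
    "write_itc_design",
]

SHIFT_COLUMNS = [
    "sample_id",
    "A_total_mM",
    "B_total_mM",
    "proton_id",
    "molecule",
    "delta_obs_ppm",
    "delta_free_ppm",
]

THERMOGRAM_COLUMNS = ["injection_index", "volume_uL", "heat", "heat_units"]

CAL_PER_JOULE = 1.0 / 4.184


def _require_columns(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_shift_table(path) -> tuple:
    """Read a shift-table CSV; returns (CVDesign, ShiftTable).

    Concentrations convert mM -> mol/L; ddelta is computed per record.  A
    sample whose A + B departs from the modal total concentration gets a
    warning attached (constant-total designs), not an error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SHIFT_COLUMNS, path)
    for col in ("A_total_mM", "B_total_mM", "delta_obs_ppm", "delta_free_ppm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = vals

    dup = df.duplicated(subset=["sample_id", "proton_id"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(
            f"{path}: duplicate (sample_id, proton_id) pair at line {row}"
        )

    sample_ids = sorted(df["sample_id"].unique())
    index_of = {s: i for i, s in enumerate(sample_ids)}
    per_sample = df.drop_duplicates("sample_id").set_index("sample_id")
    totals = (per_sample["A_total_mM"] + per_sample["B_total_mM"]) * 1e-3
    C_total = float(np.median(totals))
    if np.any(np.abs(totals - C_total) > 1e-9):
        warnings.warn(
            f"{path}: sample totals A+B deviate from the constant total "
            f"{C_total * 1e3:.4g} mM by up to "
            f"{float(np.max(np.abs(totals - C_total))) * 1e3:.3g} mM",
            UserWarning,
        )
        # keep the file's own totals; the design stores them per sample
        C_total = float(np.max(totals))
        samples = []
        for s in sample_ids:
            a = float(per_sample.loc[s, "A_total_mM"]) * 1e-3
            samples.append((a, C_total - a))
    else:
        samples = [
            (
                float(per_sample.loc[s, "A_total_mM"]) * 1e-3,
                C_total - float(per_sample.loc[s, "A_total_mM"]) * 1e-3,
            )
            for s in sample_ids
        ]
    design = CVDesign(
        samples=tuple(samples),
        C_total=C_total,
        r_values=tuple(a / C_total for a, _ in samples),
    )

    assignments = {}
    records = []
    for _, row in df.iterrows():
        pid = str(row["proton_id"])
        if pid not in assignments:
            assignments[pid] = ProtonAssignment(
                proton_id=pid,
                molecule=str(row["molecule"]),
                delta_free=float(row["delta_free_ppm"]),
            )
        records.append(
            ShiftRecord(
                sample_index=index_of[row["sample_id"]],
                proton_id=pid,
                delta_obs=float(row["delta_obs_ppm"]),
                delta_delta=float(row["delta_free_ppm"]) - float(row["delta_obs_ppm"]),
            )
        )
    return design, ShiftTable(records=records, assignments=assignments)


def write_shift_table(path, design: CVDesign, table: ShiftTable) -> None:
    """Write a shift table in the CSV dialect above (mM, ppm)."""
    rows = []
    for rec in sorted(table.records, key=lambda r: (r.sample_index, r.proton_id)):
        a, b = design.samples[rec.sample_index]
        asg = table.assignments[rec.proton_id]
        rows.append(
            {
                "sample_id": rec.sample_index,
                "A_total_mM": a * 1e3,
                "B_total_mM": b * 1e3,
                "proton_id": rec.proton_id,
                "molecule": asg.molecule,
                "delta_obs_ppm": rec.delta_obs,
                "delta_free_ppm": asg.delta_free,
            }
        )
    pd.DataFrame(rows, columns=SHIFT_COLUMNS).to_csv(path, index=False)


def read_thermogram(path, design: ITCDesign | None = None) -> tuple:
    """Read a thermogram CSV; returns (volumes_L, Thermogram with heats in cal).

    Molar ratios are taken from the design when given (and the injection
    count is checked against it), otherwise left as NaN placeholders.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, THERMOGRAM_COLUMNS, path)
    for col in ("volume_uL", "heat"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = vals
    df = df.sort_values("injection_index")

    units = df["heat_units"].astype(str).str.strip()
    bad = ~units.isin(["ucal", "uJ"])
    if bad.any():
        raise ValueError(
            f"{path}: unknown heat_units {sorted(units[bad].unique())}; "
            "expected 'ucal' or 'uJ'"
        )
    heats_cal = np.where(
        units == "ucal", df["heat"] * 1e-6, df["heat"] * 1e-6 * CAL_PER_JOULE
    )
    volumes = df["volume_uL"].to_numpy() * 1e-6

    if design is not None:
        if len(df) != len(design.injection_volumes):
            raise ValueError(
                f"{path}: {len(df)} injections in file but the design specifies "
                f"{len(design.injection_volumes)}"
            )
        dv = np.cumsum(np.asarray(design.injection_volumes))
        V0 = design.cell_volume
        M = design.cell_conc_initial * (1 - dv / (2 * V0)) / (1 + dv / (2 * V0))
        X = design.syringe_conc * (dv / V0) / (1 + dv / (2 * V0))
        ratios = tuple(X / M)
    else:
        ratios = tuple(np.full(len(df), np.nan))
    return volumes, Thermogram(heats=tuple(heats_cal), molar_ratios=ratios)


def write_thermogram(path, thermogram: Thermogram, volumes_L, units: str = "ucal") -> None:
    """Write a thermogram CSV (heats converted from cal to the given units)."""
    if units not in ("ucal", "uJ"):
        raise ValueError(f"unknown heat units {units!r}")
    factor = 1e6 if units == "ucal" else 1e6 * 4.184
    pd.DataFrame(
        {
            "injection_index": np.arange(1, len(thermogram.heats) + 1),
            "volume_uL": np.asarray(volumes_L) * 1e6,
            "heat": np.asarray(thermogram.heats) * factor,
            "heat_units": units,
        }
    ).to_csv(path, index=False)


def read_itc_design(path, injection_volumes=None) -> ITCDesign:
    """Read an ITC design JSON (mL, mM, C); unknown keys are rejected."""
    with open(path) as fh:
        cfg = json.load(fh)
    known = {"cell_volume_mL", "cell_conc_mM", "syringe_conc_mM", "temperature_C",
             "n_injections", "injection_volume_uL", "spacing_s"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"{path}: unknown design keys {sorted(unknown)}")
    for key in ("cell_volume_mL", "cell_conc_mM", "syringe_conc_mM"):
        if key not in cfg:
            raise ValueError(f"{path}: missing design key {key!r}")
    if injection_volumes is None:
        if "n_injections" not in cfg or "injection_volume_uL" not in cfg:
            raise ValueError(
                f"{path}: provide injection volumes or n_injections + "
                "injection_volume_uL"
            )
        injection_volumes = (cfg["injection_volume_uL"] * 1e-6,) * int(cfg["n_injections"])
    return ITCDesign(
        cell_volume=cfg["cell_volume_mL"] * 1e-3,
        cell_conc_initial=cfg["cell_conc_mM"] * 1e-3,
        syringe_conc=cfg["syringe_conc_mM"] * 1e-3,
        injection_volumes=tuple(injection_volumes),
        temperature=cfg.get("temperature_C", 25.0) + 273.15,
        spacing=cfg.get("spacing_s", 300.0),
    )


def write_itc_design(path, design: ITCDesign) -> None:
    vols = set(np.round(np.asarray(design.injection_volumes), 12))
    cfg = {
        "cell_volume_mL": design.cell_volume * 1e3,
        "cell_conc_mM": design.cell_conc_initial * 1e3,
        "syringe_conc_mM": design.syringe_conc * 1e3,
        "temperature_C": design.temperature - 273.15,
        "n_injections": len(design.injection_volumes),
        "injection_volume_uL": float(design.injection_volumes[0]) * 1e6,
        "spacing_s": design.spacing,
    }
    if len(vols) > 1:
        raise ValueError("design JSON supports uniform injection volumes only")
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
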
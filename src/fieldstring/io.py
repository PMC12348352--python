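"""File I/O: CSV tables, gnuplot-style grid text, JSON sidecars.

All artifacts are plain text.  Every JSON sidecar embeds a hash of the
resolved configuration so any two runs with identical config and seed can be
checked for byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import FIELD_SCAN_COLUMNS, FieldScanTable
from .pmf import PMFProfile

__all__ = ["read_field_scan", "write_field_scan", "write_grid",
           "write_profile", "write_string_trajectory", "write_json_sidecar",
           "config_hash"]


def write_field_scan(table: FieldScanTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_field_scan(path) -> FieldScanTable:
    """Read a field-scan CSV (tolerant reader: extra columns are preserved
    with a warning; missing required columns are an error)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty field-scan table")
    missing = [c for c in FIELD_SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in FIELD_SCAN_COLUMNS]
    if extra:
        warnings.warn(f"{path}: preserving unrecognized columns {extra}")
    if not np.issubdtype(df["strength_Vm"].dtype, np.number):
        raise ValueError(f"{path}: non-numeric field strengths")
    return FieldScanTable(df)


def write_grid(path, phi_axis, psi_axis, values) -> None:
    """Gnuplot-style grid text: one `phi psi F` row per node, blank line
    between phi blocks."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        for i, phi in enumerate(phi_axis):
            for j, psi in enumerate(psi_axis):
                fh.write(f"{phi:.6f} {psi:.6f} {values[i, j]:.10f}\n")
            fh.write("\n")


def write_profile(profile: PMFProfile, path) -> None:
    pd.DataFrame({"alpha": profile.alpha, "F_kJmol": profile.F}).to_csv(
        path, index=False)


def write_string_trajectory(strings, path) -> None:
    """CSV `iteration,image,phi,psi` for a sequence of StringStates."""
    rows = []
    for it, s in enumerate(strings):
        for i, (phi, psi) in enumerate(s.images):
            rows.append((it, i, phi, psi))
    pd.DataFrame(rows, columns=["iteration", "image", "phi", "psi"]).to_csv(
        path, index=False)


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json_sidecar(path, payload: dict, config_dict: dict) -> None:
    doc = dict(payload)
    doc["config_hash"] = config_hash(config_dict)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
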
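"""Tabular serialization of sweeps, readouts, and lookup tables.

CSV output is long-form with a header row, '.' decimal separator, LF line
endings, and full float precision (shortest round-trip repr), so a
re-read reproduces every value bit-for-bit. JSON mirrors the same records
as an array of objects. Row order is deterministic: ligand pKD outermost,
inhibitor pKD inner.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .assay import AssayReadout
from .scan import LookupEntry, SweepResult

__all__ = [
    "sweep_to_frame",
    "write_sweep",
    "lookup_to_frame",
    "write_lookup",
    "readout_to_dict",
    "write_readout",
]


def sweep_to_frame(result: SweepResult) -> pd.DataFrame:
    """Long-form records: ligand_pkd, inhibitor_pkd, protein_total_molar, fraction_bound."""
    records = [
        {
            "ligand_pkd": float(result.ligand_pkds[i]),
            "inhibitor_pkd": float(result.inhibitor_pkds[j]),
            "protein_total_molar": float(result.p_totals[i]),
            "fraction_bound": float(result.fraction_bound[i, j]),
        }
        for i in range(result.ligand_pkds.size)
        for j in range(result.inhibitor_pkds.size)
    ]
    return pd.DataFrame.from_records(records)


def _write_frame(frame: pd.DataFrame, path: str | Path, format: str) -> None:
    path = Path(path)
    if format == "csv":
        path.write_text(frame.to_csv(index=False, lineterminator="\n"))
    elif format == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def write_sweep(result: SweepResult, path: str | Path, format: str = "csv") -> None:
    """Write a sweep surface to ``path`` as long-form CSV or JSON records."""
    _write_frame(sweep_to_frame(result), path, format)


def lookup_to_frame(entries: list[LookupEntry]) -> pd.DataFrame:
    return pd.DataFrame.from_records([dataclasses.asdict(e) for e in entries])


def write_lookup(entries: list[LookupEntry], path: str | Path, format: str = "csv") -> None:
    """Write a lookup table of optimum probe affinities."""
    _write_frame(lookup_to_frame(entries), path, format)


def readout_to_dict(readout: AssayReadout) -> dict:
    return {
        "baseline_fraction": readout.baseline_fraction,
        "inhibited_fraction": readout.inhibited_fraction,
        "readout_reduction_percent": readout.readout_reduction_percent,
        "dynamic_range_consumed_percent": readout.dynamic_range_consumed_percent,
    }


def write_readout(readout: AssayReadout, path: str | Path) -> None:
    Path(path).write_text(json.dumps(readout_to_dict(readout), indent=1) + "\n")
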
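"""Plate dataset readers and writers.

On disk a plate is a directory of plain-text files mirroring a generic
kinetic-plate-reader export:

- ``<phase>.csv`` — one wide CSV per recording phase (``baseline``,
  ``post15``, ``post30``): first column ``time_s``, one column per well
  (header = well id, ``A01``..``H12`` style), one row per sample.
- ``layout.csv`` — columns ``well, compound, concentration_uM, role``.
- ``manifest.json`` — sampling rate, durations, seed, annotations.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .plate import PHASES, PlateDataset, TraceRecording, Treatment

__all__ = ["write_plate", "read_plate", "normalize_well_id"]

_WELL_RE = re.compile(r"^([A-Ha-h])0*(\d{1,2})$")


class PlateFormatError(ValueError):
    """Structural problem in a plate directory (wells, phases, headers)."""


class PlateParseError(ValueError):
    """Unparseable or non-finite cell in a trace file."""


def normalize_well_id(well: str) -> str:
    """Normalize well ids to the zero-padded A01..H12 convention."""
    m = _WELL_RE.match(well.strip())
    if not m:
        raise PlateFormatError(f"malformed well id: {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if not 1 <= col <= 12:
        raise PlateFormatError(f"well column out of range: {well!r}")
    return f"{row}{col:02d}"


def write_plate(dataset: PlateDataset, outdir: str | Path) -> Path:
    """Write a plate dataset; returns the directory written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wells = dataset.wells
    durations: dict[str, float] = {}
    for phase in dataset.phases:
        recs = {w: dataset.recordings[w][phase] for w in wells}
        n = {r.n_samples for r in recs.values()}
        if len(n) != 1:
            raise PlateFormatError(f"phase {phase}: unequal trace lengths across wells")
        n = n.pop()
        frame = pd.DataFrame(
            {"time_s": np.arange(n) / dataset.sampling_rate_hz}
            | {w: recs[w].samples for w in wells}
        )
        # full repr precision: the write/read round trip is exact
        frame.to_csv(outdir / f"{phase}.csv", index=False)
        durations[phase] = n / dataset.sampling_rate_hz

    layout = pd.DataFrame(
        [
            {
                "well": w,
                "compound": dataset.layout[w].compound,
                "concentration_uM": dataset.layout[w].concentration_um,
                "role": dataset.layout[w].role,
            }
            for w in wells
        ]
    )
    layout.to_csv(outdir / "layout.csv", index=False)

    manifest = {
        "sampling_rate_hz": dataset.sampling_rate_hz,
        "durations_s": durations,
        "seed": dataset.seed,
        "plate_id": dataset.plate_id,
        "phases": dataset.phases,
        "n_wells": len(wells),
        "annotations": dataset.annotations,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def _read_phase(path: Path, phase: str) -> tuple[list[str], np.ndarray, float]:
    frame = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in frame.columns:
        raise PlateFormatError(f"{path.name}: missing time_s column")
    wells = [normalize_well_id(c) for c in frame.columns if c != "time_s"]
    if len(set(wells)) != len(wells):
        raise PlateFormatError(f"{path.name}: duplicate well columns")
    values = frame.drop(columns="time_s")
    arr = values.to_numpy(dtype=float, copy=False)
    if not np.all(np.isfinite(arr)):
        rows, cols = np.nonzero(~np.isfinite(arr))
        raise PlateParseError(
            f"{path.name}: non-finite sample at row {int(rows[0]) + 2}, "
            f"column {values.columns[int(cols[0])]}"
        )
    t = frame["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise PlateFormatError(f"{path.name}: time column must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    return wells, arr, fs


def read_plate(directory: str | Path) -> PlateDataset:
    """Read a plate directory back into a PlateDataset.

    Validates that all phase files share the same wells and sampling rate,
    that samples are finite, and that time is strictly increasing.
    """
    directory = Path(directory)
    layout_path = directory / "layout.csv"
    if not layout_path.exists():
        raise PlateFormatError(f"missing layout file: {layout_path}")
    layout_frame = pd.read_csv(layout_path)
    required = {"well", "compound", "concentration_uM", "role"}
    if missing := required - set(layout_frame.columns):
        raise PlateFormatError(f"layout.csv missing columns: {sorted(missing)}")
    wells_seen: set[str] = set()
    layout: dict[str, Treatment] = {}
    for row in layout_frame.itertuples(index=False):
        well = normalize_well_id(str(row.well))
        if well in wells_seen:
            raise PlateFormatError(f"layout.csv: well {well} listed twice")
        wells_seen.add(well)
        layout[well] = Treatment(str(row.compound), float(row.concentration_uM), str(row.role))

    manifest = {}
    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())

    phase_files = [p for p in PHASES if (directory / f"{p}.csv").exists()]
    for required_phase in ("baseline", "post30"):
        if required_phase not in phase_files:
            raise PlateFormatError(f"missing required phase file: {required_phase}.csv")

    data: dict[str, dict[str, np.ndarray]] = {}
    rates: dict[str, float] = {}
    well_sets: dict[str, list[str]] = {}
    for phase in phase_files:
        wells, arr, fs = _read_phase(directory / f"{phase}.csv", phase)
        well_sets[phase] = wells
        rates[phase] = fs
        data[phase] = {w: arr[:, i] for i, w in enumerate(wells)}

    ref_wells = set(well_sets[phase_files[0]])
    for phase in phase_files[1:]:
        diff = ref_wells ^ set(well_sets[phase])
        if diff:
            raise PlateFormatError(
                f"wells differ between phases ({phase_files[0]} vs {phase}): {sorted(diff)}"
            )
    layout_diff = ref_wells ^ set(layout)
    if layout_diff:
        raise PlateFormatError(f"layout/trace well mismatch: {sorted(layout_diff)}")

    fs = float(manifest.get("sampling_rate_hz", rates[phase_files[0]]))
    for phase, rate in rates.items():
        if abs(rate - fs) / fs > 0.01:
            raise PlateFormatError(f"phase {phase}: sampling rate {rate:.3f} != {fs:.3f}")

    recordings = {
        w: {
            phase: TraceRecording(samples=data[phase][w], sampling_rate_hz=fs, phase=phase)
            for phase in phase_files
        }
        for w in sorted(ref_wells)
    }
    return PlateDataset(
        layout=layout,
        recordings=recordings,
        sampling_rate_hz=fs,
        seed=manifest.get("seed"),
        plate_id=str(manifest.get("plate_id", directory.name)),
        annotations={k: list(v) for k, v in manifest.get("annotations", {}).items()},
    )
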
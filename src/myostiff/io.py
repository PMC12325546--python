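"""Plain-text layouts for curves and traces.

Force curves are one CSV each (columns ``height_m, deflection_m``) next to a
JSON manifest describing every curve (ids, pixel coordinates, repeat, probe
calibration, condition, phase, and — for simulated data — the ground truth).
Stretch traces follow the same pattern with columns
``time_s, force_N, strain_pct``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contact import ProbeParams
from .simulate import ForceCurve, GroundTruth, StretchProtocol, StretchTrace

__all__ = [
    "write_curves",
    "read_curves",
    "write_stretch_traces",
    "read_stretch_traces",
]

MANIFEST = "manifest.json"


def _probe_dict(p: ProbeParams) -> dict:
    return dataclasses.asdict(p)


def write_curves(
    directory: str | Path,
    curves: list[ForceCurve],
    truths: list[GroundTruth] | None = None,
    extra: dict | None = None,
) -> Path:
    """Write curves as one CSV per curve plus a JSON manifest; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, c in enumerate(curves):
        fname = f"{c.curve_id}.csv"
        pd.DataFrame({"height_m": c.height, "deflection_m": c.deflection}).to_csv(
            directory / fname, index=False
        )
        entry = {
            "curve_id": c.curve_id,
            "location_id": c.location_id,
            "file": fname,
            "segment": c.segment,
            "condition": c.condition,
            "phase": c.phase,
            "probe": _probe_dict(c.probe),
        }
        if truths is not None:
            entry["ground_truth"] = dataclasses.asdict(truths[i])
        entries.append(entry)
    manifest = {"curves": entries}
    if extra:
        manifest.update(extra)
    path = directory / MANIFEST
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_curves(directory: str | Path) -> list[tuple[ForceCurve, GroundTruth | None]]:
    """Read back a curve directory written by :func:`write_curves`."""
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST).read_text())
    out = []
    for entry in manifest["curves"]:
        df = pd.read_csv(directory / entry["file"])
        curve = ForceCurve(
            curve_id=entry["curve_id"],
            location_id=entry["location_id"],
            height=df["height_m"].to_numpy(),
            deflection=df["deflection_m"].to_numpy(),
            probe=ProbeParams(**entry["probe"]),
            segment=entry.get("segment", "approach"),
            condition=entry.get("condition", "baseline"),
            phase=entry.get("phase", "pre"),
        )
        truth = (
            GroundTruth(**entry["ground_truth"]) if "ground_truth" in entry else None
        )
        out.append((curve, truth))
    return out


def write_stretch_traces(
    directory: str | Path,
    traces: list[StretchTrace],
    truths: list[dict] | None = None,
) -> Path:
    """Write stretch traces as CSVs plus a JSON manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, t in enumerate(traces):
        fname = f"{t.trace_id}.csv"
        pd.DataFrame(
            {"time_s": t.time, "force_N": t.force, "strain_pct": t.strain_command}
        ).to_csv(directory / fname, index=False)
        entry = {
            "trace_id": t.trace_id,
            "fiber_id": t.fiber_id,
            "file": fname,
            "phase": t.phase,
            "protocol": {
                "strain_levels": list(t.protocol.strain_levels),
                "hold_duration": t.protocol.hold_duration,
                "sampling_rate": t.protocol.sampling_rate,
                "normalization_mode": t.protocol.normalization_mode,
                "reference_strain": t.protocol.reference_strain,
            },
        }
        if truths is not None:
            entry["ground_truth_peaks"] = {str(k): v for k, v in truths[i].items()}
        entries.append(entry)
    path = directory / MANIFEST
    path.write_text(json.dumps({"traces": entries}, indent=2))
    return path


def read_stretch_traces(
    directory: str | Path,
) -> list[tuple[StretchTrace, dict | None]]:
    """Read back a trace directory written by :func:`write_stretch_traces`."""
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST).read_text())
    out = []
    for entry in manifest["traces"]:
        df = pd.read_csv(directory / entry["file"])
        proto = entry["protocol"]
        trace = StretchTrace(
            trace_id=entry["trace_id"],
            fiber_id=entry["fiber_id"],
            time=df["time_s"].to_numpy(),
            force=df["force_N"].to_numpy(),
            strain_command=df["strain_pct"].to_numpy(),
            protocol=StretchProtocol(
                strain_levels=tuple(proto["strain_levels"]),
                hold_duration=proto["hold_duration"],
                sampling_rate=proto["sampling_rate"],
                normalization_mode=proto["normalization_mode"],
                reference_strain=proto["reference_strain"],
            ),
            phase=entry.get("phase", "pre"),
        )
        truth = None
        if "ground_truth_peaks" in entry:
            truth = {float(k): v for k, v in entry["ground_truth_peaks"].items()}
        out.append((trace, truth))
    return out
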
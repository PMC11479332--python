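"""CSV/JSON persistence for traces, features and results."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .signal import BedModel, ForceTrace
from .simulate import CohortMember, SimulatedRecording

FORCE_HEADER = ["time_s", "LH_N", "RH_N", "LF_N", "RF_N"]


def write_force_csv(recording: SimulatedRecording, path: str | Path) -> None:
    tr = recording.force_trace
    df = pd.DataFrame(
        dict(zip(FORCE_HEADER, [tr.time, tr.LH, tr.RH, tr.LF, tr.RF]))
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_force_csv(path: str | Path) -> ForceTrace:
    df = pd.read_csv(path)
    return ForceTrace(
        df["time_s"].to_numpy(),
        df["LH_N"].to_numpy(),
        df["RH_N"].to_numpy(),
        df["LF_N"].to_numpy(),
        df["RF_N"].to_numpy(),
    )


def write_truth_csv(recording: SimulatedRecording, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": recording.force_trace.time, "tpa_deg": recording.truth_tpa}
    ).to_csv(path, index=False, float_format="%.9g")


def write_segments_json(recording: SimulatedRecording, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                dict(start=int(a), stop=int(b), target_tpa=float(t))
                for a, b, t in recording.segments
            ],
            indent=1,
        )
    )


def read_recording(
    directory: str | Path, participant_id: str, phase: str
) -> SimulatedRecording:
    directory = Path(directory)
    stem = f"{participant_id}_phase_{phase}"
    trace = read_force_csv(directory / f"{stem}_force.csv")
    truth = pd.read_csv(directory / f"{stem}_truth.csv")["tpa_deg"].to_numpy()
    segments = [
        (s["start"], s["stop"], s["target_tpa"])
        for s in json.loads((directory / f"{stem}_segments.json").read_text())
    ]
    return SimulatedRecording(trace, truth, participant_id, phase, segments)


def write_cohort(
    members: list[CohortMember], bed: BedModel, directory: str | Path
) -> None:
    """One force/truth/segments file triple per participant-phase, plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"bed": asdict(bed), "participants": {}}
    for m in members:
        for phase, rec in (("one", m.phase_one), ("two", m.phase_two)):
            stem = f"{m.participant_id}_phase_{phase}"
            write_force_csv(rec, directory / f"{stem}_force.csv")
            write_truth_csv(rec, directory / f"{stem}_truth.csv")
            write_segments_json(rec, directory / f"{stem}_segments.json")
        params = asdict(m.participant)
        params.pop("resp_angle_map", None)  # callable; not serializable
        manifest["participants"][m.participant_id] = params
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_cohort_recordings(directory: str | Path) -> list[SimulatedRecording]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    recs = []
    for pid in sorted(manifest["participants"]):
        for phase in ("one", "two"):
            recs.append(read_recording(directory, pid, phase))
    return recs


def read_bed(directory: str | Path) -> BedModel:
    manifest = json.loads((Path(directory) / "manifest.json").read_text())
    return BedModel(**manifest["bed"])


def write_results(
    results: pd.DataFrame, csv_path: str | Path, confusion_path: str | Path | None = None
) -> None:
    """Tidy metrics CSV; confusion tables to a JSON sidecar."""
    cols = [c for c in results.columns if c != "confusion"]
    results[cols].to_csv(csv_path, index=False, float_format="%.9g")
    if confusion_path is not None and "confusion" in results:
        payload = [
            {**{k: row[k] for k in ("participant", "backend", "il_level",
                                    "phase", "scheme", "side")},
             "confusion": row["confusion"]}
            for _, row in results.iterrows()
        ]
        Path(confusion_path).write_text(json.dumps(payload, indent=1))
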
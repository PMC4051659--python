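"""Plain-text I/O: recordings as CSV, plans as YAML/JSON, intervals as BED-like text.

A recording is stored as an uncompressed CSV (one row per sample, one
column per channel, header row of channel labels) next to a YAML or JSON
sidecar carrying the sample rate and the session plan; annotations travel
in a BED-like three-column text file (start s, end s, type).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montage import ChannelMontage
from .simulate import Recording, Section, SessionPlan


def plan_to_dict(plan: SessionPlan, rate: float | None = None) -> dict:
    d = {
        "cohort": plan.cohort,
        "trial_type": plan.trial_type,
        "sections": [
            {
                "start": s.start,
                "duration": s.duration,
                "task": s.task,
                "question": s.question,
                "answer": s.answer,
            }
            for s in plan.sections
        ],
    }
    if rate is not None:
        d["rate"] = rate
    return d


def plan_from_dict(d: dict) -> SessionPlan:
    sections = tuple(
        Section(
            start=float(s["start"]),
            duration=float(s["duration"]),
            task=s["task"],
            question=s.get("question"),
            answer=s.get("answer"),
        )
        for s in d["sections"]
    )
    return SessionPlan(cohort=d["cohort"], trial_type=d["trial_type"], sections=sections)


def write_plan(plan: SessionPlan, path: str | Path, rate: float | None = None) -> None:
    path = Path(path)
    d = plan_to_dict(plan, rate=rate)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def read_plan(path: str | Path) -> SessionPlan:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return plan_from_dict(d)


def write_intervals(intervals, path: str | Path) -> None:
    """BED-like 3-column text: start seconds, end seconds, type."""
    lines = [f"{a:.6f}\t{b:.6f}\t{kind}" for a, b, kind in intervals]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_intervals(path: str | Path) -> list[tuple[float, float, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        a, b, kind = line.split("\t")
        out.append((float(a), float(b), kind))
    return out


def write_recording(recording: Recording, path: str | Path, plan: SessionPlan | None = None) -> None:
    """CSV signal matrix plus sidecar plan/annotations next to it."""
    path = Path(path)
    df = pd.DataFrame(recording.data.T, columns=list(recording.montage))
    df.to_csv(path, index=False, float_format="%.6f")
    if plan is not None:
        write_plan(plan, path.with_suffix(".plan.yaml"), rate=recording.rate)
    if recording.annotations:
        write_intervals(recording.annotations, path.with_suffix(".intervals.bed"))


def read_recording(
    path: str | Path,
    fmt: str = "csv",
    montage: ChannelMontage | None = None,
    rate: float = 256.0,
) -> tuple[Recording, SessionPlan | None]:
    """Read a recording and its sidecar plan; CSV is the supported format.

    The channel labels come from the CSV header; if ``montage`` is given
    the header must match it exactly.
    """
    if fmt != "csv":
        raise ValueError(
            f"unsupported recording format {fmt!r}: only 'csv' round-trips are provided"
        )
    path = Path(path)
    df = pd.read_csv(path)
    labels = tuple(df.columns)
    if montage is not None and labels != tuple(montage):
        raise ValueError(
            f"channel header ({len(labels)} labels) does not match the expected montage "
            f"({len(montage)} labels)"
        )
    file_montage = montage if montage is not None else ChannelMontage(labels)
    plan = None
    plan_path = path.with_suffix(".plan.yaml")
    if plan_path.exists():
        d = yaml.safe_load(plan_path.read_text())
        plan = plan_from_dict(d)
        rate = float(d.get("rate", rate))
    rec = Recording(rate=rate, data=df.to_numpy().T, montage=file_montage)
    bed = path.with_suffix(".intervals.bed")
    if bed.exists():
        rec.annotations = read_intervals(bed)
    return rec, plan


def write_parameter_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_electrode_list(electrodes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(electrodes) + "\n")


def read_electrode_list(path: str | Path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


__all__ = [
    "write_plan", "read_plan", "plan_to_dict", "plan_from_dict",
    "write_intervals", "read_intervals",
    "write_recording", "read_recording",
    "write_parameter_table", "read_parameter_table",
    "write_electrode_list", "read_electrode_list",
]
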
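"""Plain-text persistence helpers for spikes, ground truth, and templates."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import NeuronGroundTruth, SpikeTrain, StateParams, Template

__all__ = [
    "write_spikes_csv",
    "read_spikes_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_templates_json",
    "read_templates_json",
]


def write_spikes_csv(trains: Iterable[SpikeTrain], path) -> None:
    frames = []
    for t in trains:
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": t.unit_id,
                    "state": t.state_label,
                    "spike_time_s": t.spike_times_s,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spikes_csv(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for (uid, state), grp in df.groupby(["unit_id", "state"], sort=True):
        trains.append(
            SpikeTrain(
                unit_id=int(uid),
                state_label=str(state),
                spike_times_s=np.sort(grp["spike_time_s"].to_numpy()),
            )
        )
    return trains


def write_ground_truth_json(population: Sequence[NeuronGroundTruth], path, seed: int | None = None) -> None:
    payload = {
        "seed": seed,
        "units": [dataclasses.asdict(n) for n in population],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_json(path) -> list[NeuronGroundTruth]:
    payload = json.loads(Path(path).read_text())
    out = []
    for u in payload["units"]:
        out.append(
            NeuronGroundTruth(
                unit_id=u["unit_id"],
                recording_id=u["recording_id"],
                remodel_class=u["remodel_class"],
                wake=StateParams(**u["wake"]),
                anesthesia=StateParams(**u["anesthesia"]),
            )
        )
    return out


def write_templates_json(templates: Sequence[Template], path) -> None:
    payload = [
        {
            "unit_id": t.unit_id,
            "recording_id": t.recording_id,
            "peak_channel": t.peak_channel,
            "waveform": np.round(t.waveform, 4).tolist(),
        }
        for t in templates
    ]
    Path(path).write_text(json.dumps(payload))


def read_templates_json(path) -> list[Template]:
    payload = json.loads(Path(path).read_text())
    return [
        Template(
            unit_id=int(t["unit_id"]),
            recording_id=int(t["recording_id"]),
            waveform=np.asarray(t["waveform"], dtype=float),
            peak_channel=int(t["peak_channel"]),
        )
        for t in payload
    ]
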
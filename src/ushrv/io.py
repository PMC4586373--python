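"""File formats: the tabular NN dialect, a one-interval-per-line text
format, and YAML/JSON generator configs.

The tabular dialect is a TSV with columns ``subject_id, beat_time_s, nn_ms,
flag`` — one row per interval, ``beat_time_s`` being the interval's
*terminating* beat time. The leading beat time of each subject is recovered
as ``beat_time_s[0] - nn_ms[0] / 1000``. The single-subject text format
(one NN interval in milliseconds per line) matches the plain-text RR/NN
dumps common in public ECG archives.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .series import FLAG_NORMAL, NNSeries
from .synth import PopulationSpec

PathLike = Union[str, Path]


def write_nn_table(series_list: Sequence[NNSeries], path: PathLike) -> None:
    """Write recordings to the tabular NN dialect (TSV)."""
    rows = []
    for s in series_list:
        term = s.beat_times[1:]
        for t, nn, fl in zip(term, s.intervals, s.flags):
            rows.append((s.subject_id, f"{t:.6f}", f"{nn:.6f}", fl))
    df = pd.DataFrame(rows, columns=["subject_id", "beat_time_s", "nn_ms", "flag"])
    df.to_csv(path, sep="\t", index=False)


def read_nn_table(path: PathLike) -> List[NNSeries]:
    """Read recordings from the tabular NN dialect, preserving subject order."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    out: List[NNSeries] = []
    for sid, g in df.groupby("subject_id", sort=False):
        term = g["beat_time_s"].to_numpy(float)
        nn = g["nn_ms"].to_numpy(float)
        flags = g["flag"].to_numpy(object)
        first = term[0] - nn[0] / 1000.0
        beat_times = np.concatenate([[first], term])
        out.append(NNSeries(str(sid), beat_times, nn, flags))
    return out


def write_nn_text(series: NNSeries, path: PathLike) -> None:
    """Write one subject as plain text: one NN interval (ms) per line."""
    Path(path).write_text(
        "".join(f"{x:.6f}\n" for x in series.intervals), encoding="ascii")


def read_nn_text(path: PathLike, subject_id: str = "S0") -> NNSeries:
    """Read a one-interval-per-line text file; flags default to normal."""
    iv = [float(line) for line in Path(path).read_text().split()]
    return NNSeries.from_intervals(subject_id, iv)


def population_spec_to_dict(spec: PopulationSpec) -> dict:
    return {
        "n_subjects": spec.n_subjects,
        "seed": spec.seed,
        "params_distribution": {k: list(v) for k, v in spec.params_distribution.items()},
    }


def population_spec_from_dict(d: dict) -> PopulationSpec:
    dist = {k: tuple(v) for k, v in d.get("params_distribution", {}).items()}
    spec = PopulationSpec(n_subjects=int(d["n_subjects"]),
                          params_distribution=dist,
                          seed=int(d.get("seed", 0)))
    spec.validate()
    return spec


def load_population_spec(path: PathLike) -> PopulationSpec:
    """Load a PopulationSpec from a YAML or JSON file."""
    text = Path(path).read_text()
    d = yaml.safe_load(text)
    return population_spec_from_dict(d)


def save_population_spec(spec: PopulationSpec, path: PathLike) -> None:
    p = Path(path)
    d = population_spec_to_dict(spec)
    if p.suffix == ".json":
        p.write_text(json.dumps(d, indent=2))
    else:
        p.write_text(yaml.safe_dump(d, sort_keys=False))
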
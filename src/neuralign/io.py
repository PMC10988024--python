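"""HDF5 serialization of datasets, intermediate arrays and fitted filters.

Dataset layout (one group per file):

* ``/data``     — subjects × channels × samples float array
* ``/events``   — (n_events, 2) int start/stop table plus a ``labels`` attr
* ``/meta``     — group with ``group``, ``sampling_rate`` and ``processing``
                  (list of applied preprocessing steps) attributes

Filter files carry ``/filters`` (subjects × channels × K), ``/eigenvalues``
and ``/patterns`` with fit configuration stored as attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .mcca import MCCAResults
from .preprocess import Event, SubjectRecording
from .simulate import MultiSubjectDataset

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_filters",
    "load_filters",
]


def save_dataset(path, dataset: MultiSubjectDataset, processing: list[str] | None = None) -> None:
    data = np.stack([rec.data for rec in dataset.recordings])
    events = dataset.events
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data, compression="gzip", compression_opts=1)
        ev = f.create_dataset(
            "events", data=np.array([(e.start, e.stop) for e in events], dtype=np.int64)
        )
        ev.attrs["labels"] = json.dumps([e.label for e in events])
        meta = f.create_group("meta")
        meta.attrs["group"] = dataset.group
        meta.attrs["sampling_rate"] = dataset.sampling_rate
        meta.attrs["processing"] = json.dumps(processing or [])


def load_dataset(path) -> MultiSubjectDataset:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        spans = f["events"][()]
        labels = json.loads(f["events"].attrs["labels"])
        events = [Event(int(a), int(b), lab) for (a, b), lab in zip(spans, labels)]
        group = f["meta"].attrs["group"]
        fs = float(f["meta"].attrs["sampling_rate"])
    recs = [SubjectRecording(data=x, sampling_rate=fs, events=list(events)) for x in data]
    return MultiSubjectDataset(group=str(group), recordings=recs)


def save_filters(path, results: MCCAResults, provenance: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("filters", data=results.filters)
        f.create_dataset("eigenvalues", data=results.eigenvalues)
        f.create_dataset("patterns", data=results.patterns)
        f.attrs["n_subjects"] = results.n_subjects
        f.attrs["gamma"] = results.gamma
        f.attrs["provenance"] = json.dumps(provenance or {})


def load_filters(path) -> MCCAResults:
    with h5py.File(path, "r") as f:
        return MCCAResults(
            filters=f["filters"][()],
            eigenvalues=f["eigenvalues"][()],
            patterns=f["patterns"][()],
            n_subjects=int(f.attrs["n_subjects"]),
            gamma=float(f.attrs["gamma"]),
        )
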
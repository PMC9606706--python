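"""Persistence helpers: dense arrays with JSON sidecars.

Leadfields, epochs and inverse operators are exchanged as ``.npy`` arrays
next to a ``.json`` sidecar holding units, timing and provenance. Montages
travel as TSV (see :mod:`pacsim.geometry`); results tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .forward import Leadfield
from .inverse import InverseOperator
from .simulate import SensorEpochs

__all__ = [
    "save_leadfield",
    "load_leadfield",
    "save_epochs",
    "load_epochs",
    "save_inverse_operator",
    "load_inverse_operator",
]


def save_leadfield(lf: Leadfield, path_prefix) -> None:
    prefix = Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), lf.gain)
    sidecar = {
        "units": "V per (A.m)",
        "channel_labels": list(lf.channel_labels),
        "n_sources": lf.n_sources,
        "head_ref": lf.head_ref,
        "montage_ref": lf.montage_ref,
        "sourcespace_ref": lf.sourcespace_ref,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_leadfield(path_prefix) -> Leadfield:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return Leadfield(
        gain=np.load(prefix.with_suffix(".npy")),
        channel_labels=tuple(meta["channel_labels"]),
        n_sources=meta["n_sources"],
        head_ref=meta["head_ref"],
        montage_ref=meta["montage_ref"],
        sourcespace_ref=meta["sourcespace_ref"],
    )


def save_inverse_operator(op: InverseOperator, path_prefix) -> None:
    prefix = Path(path_prefix)
    np.save(prefix.with_suffix(".kernel.npy"), op.kernel)
    np.save(prefix.with_suffix(".norms.npy"), op.norm_factors)
    sidecar = {
        "method": op.method,
        "depth_order": op.depth_order,
        "snr": op.snr,
        "channel_labels": list(op.channel_labels),
        "sourcespace_ref": op.sourcespace_ref,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_inverse_operator(path_prefix) -> InverseOperator:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return InverseOperator(
        kernel=np.load(prefix.with_suffix(".kernel.npy")),
        norm_factors=np.load(prefix.with_suffix(".norms.npy")),
        method=meta["method"],
        depth_order=meta["depth_order"],
        snr=meta["snr"],
        channel_labels=tuple(meta["channel_labels"]),
        sourcespace_ref=meta["sourcespace_ref"],
    )


def save_epochs(epochs: SensorEpochs, path_prefix) -> None:
    prefix = Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), epochs.data)
    sidecar = {
        "units": "V",
        "fs_hz": epochs.fs,
        "epoch_window_s": list(epochs.epoch_window),
        "channel_labels": list(epochs.channel_labels),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epochs(path_prefix) -> SensorEpochs:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return SensorEpochs(
        data=np.load(prefix.with_suffix(".npy")),
        fs=meta["fs_hz"],
        epoch_window=tuple(meta["epoch_window_s"]),
        channel_labels=tuple(meta["channel_labels"]),
    )
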
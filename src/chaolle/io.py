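"""Epoch container and model serialization.

Epoch sets travel as HDF5 files with datasets ``/data``
(epochs x channels x samples), ``/labels``, ``/fs`` and ``/channel_names``;
a CSV export (one epoch per file, channels as columns) is provided for
interoperability with spreadsheet-level tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .preprocess import EpochSet

__all__ = ["write_epochs_h5", "read_epochs_h5", "export_epochs_csv",
           "save_model", "load_model"]


def write_epochs_h5(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("fs", data=float(epochs.fs))
        f.create_dataset("channel_names",
                         data=np.array(epochs.channel_names, dtype="S"))
        f.create_dataset("window", data=np.asarray(epochs.window, dtype=float))


def read_epochs_h5(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            labels=f["labels"][()],
            fs=float(f["fs"][()]),
            channel_names=[c.decode() for c in f["channel_names"][()]],
            window=tuple(f["window"][()]) if "window" in f else (200.0, 2500.0),
        )


def export_epochs_csv(epochs: EpochSet, out_dir: str | Path) -> list[Path]:
    """One CSV per epoch (samples x channels), named epoch_<k>_<label>.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(epochs.n_epochs):
        p = out_dir / f"epoch_{k:04d}_label{epochs.labels[k]}.csv"
        header = ",".join(epochs.channel_names)
        np.savetxt(p, epochs.data[k].T, delimiter=",", header=header,
                   comments="")
        paths.append(p)
    return paths


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted GRBFSVC as JSON metadata + an .npz array bundle.

    The training set is stored; ``load_model`` refits on it, which is
    exact because the dual solution is deterministic given the data.
    """
    path = Path(path)
    meta = {
        "C": model.C, "sigma": model.sigma, "tau": model.tau,
        "center": np.atleast_1d(model.center).tolist(),
        "classes": model.classes_.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.savez(path.with_suffix(".npz"), X_fit=model.X_fit_, y_fit=model.y_fit_)


def load_model(path: str | Path):
    """Rebuild a GRBFSVC saved by :func:`save_model`."""
    from .classify import GRBFSVC
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    model = GRBFSVC(C=meta["C"], sigma=meta["sigma"], tau=meta["tau"],
                    center=np.asarray(meta["center"]))
    return model.fit(arrays["X_fit"], arrays["y_fit"])
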
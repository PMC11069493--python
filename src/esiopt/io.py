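"""Plain-text and array-container persistence for all core types.

Conventions: montages as ``.sfp``-style whitespace text (label x y z, meters);
lead fields and epoch sets as ``.npz`` array containers with a JSON sidecar
(``<stem>.json``) carrying labels and provenance; tables as CSV.  Every
writer/reader pair round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .headmodel import LeadField, Montage, ShellModel, SourceSpace
from .optimize import Nsga2Result
from .simulate import EpochSet

__all__ = [
    "write_montage_sfp",
    "read_montage_sfp",
    "save_leadfield",
    "load_leadfield",
    "save_epochs",
    "load_epochs",
    "archive_to_frame",
    "write_archive_csv",
    "write_pareto_csv",
    "write_best_per_count_json",
]


def write_montage_sfp(montage: Montage, path) -> None:
    lines = [
        f"{label}\t{p[0]:.17g}\t{p[1]:.17g}\t{p[2]:.17g}"
        for label, p in zip(montage.labels, montage.positions)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_montage_sfp(path, system: str = "custom") -> Montage:
    labels, pos = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed montage row: {line!r}")
        labels.append(parts[0])
        pos.append([float(v) for v in parts[1:]])
    return Montage(tuple(labels), np.array(pos), system)


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def save_leadfield(lf: LeadField, path, extra: dict | None = None) -> None:
    path = Path(path)
    np.savez(
        path,
        gain=lf.gain,
        positions=lf.montage.positions,
        src_positions=lf.source_space.positions,
        src_orientations=lf.source_space.orientations,
    )
    shell = lf.shell or ShellModel()
    meta = {
        "labels": list(lf.montage.labels),
        "system": lf.montage.system,
        "hemisphere": lf.source_space.hemisphere.tolist(),
        "n_per_hemisphere": lf.source_space.n_per_hemisphere,
        "radii": list(shell.radii),
        "conductivities": list(shell.conductivities),
        "series_terms": shell.series_terms,
    }
    meta.update(extra or {})
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_leadfield(path) -> LeadField:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    arrays = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    montage = Montage(tuple(meta["labels"]), arrays["positions"], meta["system"])
    src = SourceSpace(
        arrays["src_positions"],
        arrays["src_orientations"],
        np.array(meta["hemisphere"]),
        int(meta["n_per_hemisphere"]),
    )
    shell = ShellModel(
        tuple(meta["radii"]), tuple(meta["conductivities"]), int(meta["series_terms"])
    )
    return LeadField(arrays["gain"], montage, src, shell)


def save_epochs(epochs: EpochSet, path) -> None:
    path = Path(path)
    np.savez(path, data=epochs.data, truth=epochs.truth)
    meta = {
        "sfreq": epochs.sfreq,
        "snr_db": epochs.snr_db,
        "meta": epochs.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_epochs(path) -> EpochSet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    arrays = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    return EpochSet(
        arrays["data"], meta["sfreq"], arrays["truth"], meta["snr_db"], meta["meta"]
    )


def epochs_metadata_frame(epochs: EpochSet) -> pd.DataFrame:
    """Per-trial metadata table (CSV-exportable)."""
    return pd.DataFrame(
        {
            "trial": np.arange(epochs.n_trials),
            "truth": epochs.truth,
            "snr_db": epochs.snr_db if epochs.snr_db is not None else np.nan,
        }
    )


def archive_to_frame(result: Nsga2Result, montage) -> pd.DataFrame:
    rows = [
        {
            "channels": ";".join(rec.mask.labels(montage)),
            "mean_loc_error_mm": rec.mean_loc_error,
            "n_channels": rec.n_channels,
            "generation_found": rec.generation_found,
        }
        for rec in result.archive
    ]
    return pd.DataFrame(rows, columns=["channels", "mean_loc_error_mm", "n_channels", "generation_found"])


def write_archive_csv(result: Nsga2Result, montage, path) -> None:
    archive_to_frame(result, montage).to_csv(path, index=False)


def write_pareto_csv(result: Nsga2Result, montage, path) -> None:
    front = result.pareto_front()
    pd.DataFrame(
        {
            "n_channels": [r.n_channels for r in front],
            "mean_loc_error_mm": [r.mean_loc_error for r in front],
            "channels": [";".join(r.mask.labels(montage)) for r in front],
        }
    ).to_csv(path, index=False)


def write_best_per_count_json(result: Nsga2Result, montage, path) -> None:
    payload = {
        str(count): {
            "channels": rec.mask.labels(montage),
            "mean_loc_error_mm": rec.mean_loc_error,
            "generation_found": rec.generation_found,
        }
        for count, rec in result.best_per_count().items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
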
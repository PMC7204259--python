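"""Delimited text formats for time-series streams and session manifests.

Every stream is a plain comma-delimited file with a commented header that
carries the metadata the pipeline needs:

    # rate: 2000.0
    # kind: emg
    # condition: comfortable_max
    # channels: ECR,ECU,FCU,FCR,APL,FDS,FDP
    0.01,0.02,...

A session directory holds one file per stream plus a ``manifest.yaml``
listing the trials, their conditions and provenance (seed, config hash).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import yaml

from .exceptions import FormatError
from .simulate import Session, Trial, TrialSpec

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_session",
    "read_session",
    "config_hash",
]

_REQUIRED_HEADER = ("rate", "channels")


def write_timeseries(
    path, data: np.ndarray, rate: float, channels, **metadata
) -> None:
    """Write a time-by-channel matrix with its header metadata."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 1 and data.shape[1] > len(list(channels)):
        data = data.T
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rate: {float(rate)}\n")
        fh.write(f"# channels: {','.join(channels)}\n")
        for key, value in metadata.items():
            fh.write(f"# {key}: {value}\n")
        for row in data:
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")


def read_timeseries(path) -> tuple[np.ndarray, dict]:
    """Read a delimited stream; malformed rows are reported by line number."""
    path = Path(path)
    meta = {}
    rows = []
    ncols = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split(",")
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise FormatError(
                    f"{path.name}: expected {ncols} columns on line {lineno}, "
                    f"found {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}: non-numeric value on line {lineno}: {exc}"
                ) from None
    for key in _REQUIRED_HEADER:
        if key not in meta:
            raise FormatError(f"{path.name}: missing header field '# {key}:'")
    if not rows:
        raise FormatError(f"{path.name}: empty data section")
    meta["rate"] = float(meta["rate"])
    meta["channels"] = tuple(c.strip() for c in meta["channels"].split(","))
    return np.asarray(rows, dtype=float), meta


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    blob = yaml.safe_dump(obj, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_session(session: Session, outdir, extra_meta: dict | None = None) -> Path:
    """Write every trial's streams plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = session.ground_truth.channel_labels
    entries = []
    for i, trial in enumerate(session.trials):
        stem = f"trial{i:02d}"
        entry = {"condition": trial.condition, "seed": int(trial.seed)}
        emg_path = outdir / f"{stem}_emg.csv"
        write_timeseries(
            emg_path, trial.emg, trial.emg_rate, labels,
            kind="emg", condition=trial.condition,
        )
        entry["emg"] = emg_path.name
        ang_path = outdir / f"{stem}_angles.csv"
        write_timeseries(
            ang_path, trial.angles, trial.angle_rate, ("angle_x", "angle_y"),
            kind="angles", condition=trial.condition,
        )
        entry["angles"] = ang_path.name
        if trial.force is not None:
            f_path = outdir / f"{stem}_force.csv"
            write_timeseries(
                f_path, trial.force, trial.force_rate, ("force",),
                kind="force", condition=trial.condition,
            )
            entry["force"] = f_path.name
        entries.append(entry)
    manifest = {
        "provenance": {
            "generator": "wristsyn.simulate",
            "seed": int(session.seed),
            "ground_truth_seed": int(session.ground_truth.seed),
            **(extra_meta or {}),
        },
        "channels": list(labels),
        "trials": entries,
    }
    mpath = outdir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath


def read_session(directory) -> list[dict]:
    """Load the trials of a written session.

    Returns one dict per trial with keys ``condition``, ``emg``/``emg_rate``,
    ``angles``/``angle_rate`` and optionally ``force``/``force_rate``.
    """
    directory = Path(directory)
    mpath = directory / "manifest.yaml"
    if not mpath.exists():
        raise FormatError(f"no manifest.yaml in {directory}")
    manifest = yaml.safe_load(mpath.read_text())
    trials = []
    for entry in manifest["trials"]:
        out = {"condition": entry["condition"]}
        for stream in ("emg", "angles", "force"):
            if stream not in entry:
                continue
            fpath = directory / entry[stream]
            if not fpath.exists():
                raise FormatError(f"manifest references missing file {fpath.name}")
            data, meta = read_timeseries(fpath)
            out[stream] = data if stream != "force" else data[:, 0]
            out[f"{stream}_rate"] = meta["rate"]
        trials.append(out)
    return trials
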
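"""Persistence: HDF5 containers, JSON masks/ground truth, table exports.

HDF5 layout for cohorts::

    /participant_0/data      float (channels x samples)
    /participant_0/fs        scalar
    /participant_0/meta/<column>   per-channel metadata arrays
    ...

Artifact masks are stored as run-length-encoded intervals in JSON;
connectivity matrices and embeddings as HDF5 datasets with labels and
parameters; dendrograms as Newick with linkage heights as branch lengths.
A :class:`RunManifest` snapshots config, seeds, and content hashes so a
run can be reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time

import h5py
import numpy as np
import pandas as pd

from .types import ArtifactMask, ConnectivityMatrix, Recording

__all__ = [
    "write_cohort",
    "read_recording",
    "read_cohort",
    "mask_to_intervals",
    "intervals_to_mask",
    "write_mask",
    "read_mask",
    "write_connectivity",
    "read_connectivity",
    "write_embedding",
    "export_tables",
    "linkage_to_newick",
    "RunManifest",
    "array_hash",
]

_META_COLS = ("participant", "roi", "hemisphere")


def _write_meta(grp: h5py.Group, meta: pd.DataFrame) -> None:
    mg = grp.create_group("meta")
    for col in meta.columns:
        vals = meta[col].to_numpy()
        if vals.dtype == object or str(vals.dtype).startswith("str"):
            vals = np.array([str(v) for v in vals], dtype="S64")
        mg.create_dataset(col, data=vals)


def _read_meta(grp: h5py.Group) -> pd.DataFrame:
    cols = {}
    for col in grp:
        v = grp[col][()]
        if v.dtype.kind == "S":
            v = np.array([s.decode() for s in v])
        cols[col] = v
    return pd.DataFrame(cols)


def write_cohort(path, recordings: list[Recording]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_participants"] = len(recordings)
        for i, rec in enumerate(recordings):
            g = f.create_group(f"participant_{i}")
            g.create_dataset("data", data=rec.data, compression="gzip",
                             compression_opts=1)
            g.create_dataset("fs", data=float(rec.fs))
            _write_meta(g, rec.channel_meta)


def read_recording(path, fmt: str = "hdf5", participant: int = 0
                   ) -> Recording:
    """Read one participant's recording from HDF5 (or an EDF file)."""
    if fmt == "edf":
        return _read_edf(path)
    with h5py.File(path, "r") as f:
        key = f"participant_{participant}"
        if key not in f:
            raise KeyError(f"{key} not present in {path}")
        g = f[key]
        meta = _read_meta(g["meta"])
        missing = [c for c in _META_COLS if c not in meta.columns]
        if missing:
            raise ValueError(
                f"channel metadata missing required column(s): {missing}")
        rec = Recording(data=g["data"][()], fs=float(g["fs"][()]),
                        channel_meta=meta)
    return rec


def read_cohort(path) -> list[Recording]:
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_participants"])
    return [read_recording(path, participant=i) for i in range(n)]


def _read_edf(path) -> Recording:
    import mne  # optional dependency, EDF interoperability only

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    meta = pd.DataFrame({
        "participant": ["edf"] * data.shape[0],
        "roi": raw.ch_names,
        "hemisphere": ["?"] * data.shape[0],
    })
    if len(raw.ch_names) != data.shape[0]:  # pragma: no cover - mne invariant
        raise ValueError(
            f"EDF channel count {data.shape[0]} does not match metadata "
            f"count {len(raw.ch_names)}")
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     channel_meta=meta)


def mask_to_intervals(mask: ArtifactMask) -> dict:
    """Run-length encode a boolean mask as per-channel [start, stop) lists."""
    out = {}
    m = mask.mask
    for ch in range(m.shape[0]):
        x = m[ch].astype(np.int8)
        d = np.diff(np.concatenate(([0], x, [0])))
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        out[str(ch)] = [[int(a), int(b)] for a, b in zip(starts, stops)]
    return {"n_channels": m.shape[0], "n_samples": m.shape[1],
            "intervals": out}


def intervals_to_mask(payload: dict) -> ArtifactMask:
    m = np.zeros((payload["n_channels"], payload["n_samples"]), dtype=bool)
    for ch, runs in payload["intervals"].items():
        for a, b in runs:
            m[int(ch), a:b] = True
    return ArtifactMask(m)


def write_mask(path, mask: ArtifactMask) -> None:
    with open(path, "w") as f:
        json.dump(mask_to_intervals(mask), f)


def read_mask(path) -> ArtifactMask:
    with open(path) as f:
        return intervals_to_mask(json.load(f))


def write_connectivity(path, conn: ConnectivityMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=conn.values)
        f.create_dataset("missing", data=conn.missing)
        f.create_dataset("labels",
                         data=np.array([str(l) for l in conn.node_labels],
                                       dtype="S64"))
        f.attrs.update({"level": conn.level, "band": conn.band,
                        "measure": conn.measure,
                        "n_segments_used": conn.n_segments_used})


def read_connectivity(path) -> ConnectivityMatrix:
    with h5py.File(path, "r") as f:
        labels = [s.decode() for s in f["labels"][()]]
        return ConnectivityMatrix(
            values=f["values"][()], missing=f["missing"][()],
            node_labels=labels, level=f.attrs["level"],
            band=f.attrs["band"], measure=f.attrs["measure"],
            n_segments_used=int(f.attrs["n_segments_used"]))


def write_embedding(path, emb) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=emb.coords)
        f.create_dataset("spectrum", data=emb.spectrum)
        f.create_dataset("basis", data=emb.basis)
        f.create_dataset("labels",
                         data=np.array([str(l) for l in emb.node_labels],
                                       dtype="S64"))
        f.attrs.update({"t": str(emb.t), "k_infl": emb.k_infl})


def linkage_to_newick(linkage: np.ndarray, labels: list) -> str:
    """Newick string from a scipy linkage matrix, heights as branch lengths."""
    z = np.asarray(linkage)
    n = z.shape[0] + 1
    height = {i: 0.0 for i in range(n)}

    def build(node: int) -> str:
        if node < n:
            return str(labels[node]).replace(" ", "_")
        row = z[node - n]
        h = row[2]
        kids = []
        for c in (int(row[0]), int(row[1])):
            ch = height[c] if c < n else z[c - n][2]
            kids.append(f"{build(c)}:{max(h - ch, 0.0):.6g}")
        return "(" + ",".join(kids) + ")"

    return build(2 * n - 2) + ";"


def export_tables(results: dict, out_dir) -> list:
    """Write DataFrames as TSV, dicts as JSON, newick strings as .nwk."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = os.path.join(out_dir, f"{name}.tsv")
            obj.to_csv(p, sep="\t", float_format="%.12g")
        elif isinstance(obj, str) and obj.rstrip().endswith(";"):
            p = os.path.join(out_dir, f"{name}.nwk")
            with open(p, "w") as f:
                f.write(obj)
        else:
            p = os.path.join(out_dir, f"{name}.json")
            with open(p, "w") as f:
                json.dump(obj, f, indent=2, default=_json_default)
        written.append(p)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def array_hash(arr: np.ndarray) -> str:
    a = np.ascontiguousarray(arr)
    return hashlib.sha256(a.tobytes()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Snapshot sufficient to reproduce a pipeline run bit for bit."""

    config: dict
    seed: int
    stages: list = dataclasses.field(default_factory=list)
    hashes: dict = dataclasses.field(default_factory=dict)
    timestamps: dict = dataclasses.field(default_factory=dict)

    def record(self, stage: str, **arrays) -> None:
        self.stages.append(stage)
        self.timestamps[stage] = time.time()
        for name, arr in arrays.items():
            self.hashes[f"{stage}/{name}"] = array_hash(np.asarray(arr))

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2,
                      default=_json_default)
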
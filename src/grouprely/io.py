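"""Readers and writers for the on-disk formats.

Formats:

* **Epochs bundle (HDF5)** — datasets ``/data`` (trial x channel x sample),
  ``/labels``, ``/srate``, ``/channels/names``, ``/channels/pos`` and the
  optional ``/session_id`` / ``/block_id``.
* **Feature table (TSV + JSON sidecar)** — header
  ``trial_id<TAB>label<TAB><predictor columns...>``; the sidecar maps each
  predictor column name to ``{"channel_name": ..., "frequency_hz": ...}``.
* **Group spec (JSON)** — mapping of group name to either an explicit 0-based
  index list or a declarative selector (``{"frequency_hz": [lo, hi]}``
  inclusive, ``{"channels": [...]}``, optionally combined).
* **Channel layout (JSON)** — list of ``{"name", "x", "y", "roi"}`` records.

``write_epochs`` / ``read_epochs`` round-trip bit-exactly: floats are stored
in their native binary width, labels and ids as integers.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import (
    ChannelLayout,
    FeatureMatrix,
    GroupSpec,
    PredictorMeta,
    TrialEpochs,
    ValidationError,
)

__all__ = [
    "FormatError",
    "read_epochs",
    "write_epochs",
    "read_feature_table",
    "write_feature_table",
    "read_group_spec",
    "write_group_spec",
    "read_layout",
    "write_layout",
]


class FormatError(ValueError):
    """A file does not follow the expected on-disk layout."""


_REQUIRED_DATASETS = ("data", "labels", "srate", "channels/names", "channels/pos")


def read_epochs(path: str | Path) -> TrialEpochs:
    """Read an HDF5 epochs bundle into a validated :class:`TrialEpochs`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for ds in _REQUIRED_DATASETS:
            if ds not in f:
                raise FormatError(f"{path}: missing required dataset /{ds}")
        data = f["data"][()]
        labels = f["labels"][()]
        srate = float(np.asarray(f["srate"][()]).item())
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f["channels/names"][()]]
        pos = f["channels/pos"][()]
        session_id = f["session_id"][()] if "session_id" in f else None
        block_id = f["block_id"][()] if "block_id" in f else None
    return TrialEpochs(
        data=data, srate=srate, channel_names=names, channel_pos=pos,
        labels=labels, session_id=session_id, block_id=block_id,
    )


def write_epochs(epochs: TrialEpochs, path: str | Path) -> Path:
    """Write a :class:`TrialEpochs` to an HDF5 bundle; returns the path."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("srate", data=float(epochs.srate))
        f.create_dataset(
            "channels/names",
            data=np.array(epochs.channel_names, dtype=h5py.string_dtype()),
        )
        f.create_dataset("channels/pos", data=epochs.channel_pos)
        if epochs.session_id is not None:
            f.create_dataset("session_id", data=epochs.session_id)
        if epochs.block_id is not None:
            f.create_dataset("block_id", data=epochs.block_id)
    return path


def _predictor_column_name(m: PredictorMeta) -> str:
    if m.frequency_hz is not None:
        return f"{m.channel_name}_{m.frequency_hz}Hz"
    return m.tag if m.tag is not None else m.channel_name


def write_feature_table(
    fm: FeatureMatrix, tsv_path: str | Path, meta_path: str | Path
) -> tuple[Path, Path]:
    """Write a feature matrix as TSV plus a JSON predictor-metadata sidecar."""
    tsv_path, meta_path = Path(tsv_path), Path(meta_path)
    cols = [_predictor_column_name(m) for m in fm.meta]
    if len(set(cols)) != len(cols):
        raise ValidationError("meta: predictor column names are not unique")
    df = pd.DataFrame(fm.X, columns=cols)
    df.insert(0, "label", fm.y)
    df.insert(0, "trial_id", np.arange(fm.n_trials))
    df.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    sidecar = {
        c: {
            "channel_name": m.channel_name,
            "frequency_hz": m.frequency_hz,
            "tag": m.tag,
        }
        for c, m in zip(cols, fm.meta)
    }
    meta_path.write_text(json.dumps(sidecar, indent=1) + "\n", encoding="utf-8")
    return tsv_path, meta_path


def read_feature_table(tsv_path: str | Path, meta_path: str | Path) -> FeatureMatrix:
    """Read a TSV feature table and its JSON sidecar; column order preserved."""
    tsv_path, meta_path = Path(tsv_path), Path(meta_path)
    df = pd.read_csv(tsv_path, sep="\t")
    for required in ("trial_id", "label"):
        if required not in df.columns:
            raise FormatError(f"{tsv_path}: missing required column {required!r}")
    predictor_cols = [c for c in df.columns if c not in ("trial_id", "label")]
    sidecar = json.loads(meta_path.read_text(encoding="utf-8"))
    missing = [c for c in predictor_cols if c not in sidecar]
    extra = [c for c in sidecar if c not in predictor_cols]
    if missing or extra:
        raise ValidationError(
            f"sidecar/column mismatch: columns without metadata {missing}, "
            f"metadata without columns {extra}"
        )
    meta = []
    for c in predictor_cols:
        rec = sidecar[c]
        freq = rec.get("frequency_hz")
        meta.append(
            PredictorMeta(
                channel_name=str(rec.get("channel_name", c)),
                frequency_hz=None if freq is None else int(freq),
                tag=rec.get("tag"),
            )
        )
    return FeatureMatrix(
        X=df[predictor_cols].to_numpy(dtype=float),
        y=df["label"].to_numpy(),
        meta=meta,
    )


def _resolve_selector(name: str, sel: dict, meta: list[PredictorMeta]) -> np.ndarray:
    """Resolve a declarative selector against predictor metadata."""
    known = {"frequency_hz", "channels"}
    unknown = set(sel) - known
    if unknown:
        raise FormatError(
            f"group {name!r}: unknown selector key(s) {sorted(unknown)}; "
            f"expected one of {sorted(known)}"
        )
    mask = np.ones(len(meta), dtype=bool)
    if "frequency_hz" in sel:
        lo, hi = sel["frequency_hz"]
        freqs = np.array(
            [m.frequency_hz if m.frequency_hz is not None else -1 for m in meta]
        )
        mask &= (freqs >= int(lo)) & (freqs <= int(hi))
    if "channels" in sel:
        chans = set(map(str, sel["channels"]))
        mask &= np.array([m.channel_name in chans for m in meta])
    return np.flatnonzero(mask)


def read_group_spec(json_path: str | Path, meta: list[PredictorMeta]) -> GroupSpec:
    """Read a JSON group spec, resolving selectors against predictor metadata.

    Explicit index lists are 0-based.  An empty resolved group is an error
    naming the group.
    """
    json_path = Path(json_path)
    raw = json.loads(json_path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise FormatError(f"{json_path}: expected a JSON object at top level")
    groups: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for name, body in raw.items():
        if isinstance(body, dict):
            kind = body.pop("kind", "custom")
            idx = _resolve_selector(name, body, meta)
        else:
            kind = "custom"
            idx = np.asarray(body, dtype=np.int64)
        if idx.size == 0:
            raise ValidationError(f"group {name!r}: resolves to an empty index set")
        groups[name] = idx
        kinds[name] = str(kind)
    return GroupSpec(groups=groups, kinds=kinds, n_predictors=len(meta))


def write_group_spec(spec: GroupSpec, json_path: str | Path) -> Path:
    json_path = Path(json_path)
    payload = {name: [int(i) for i in idx] for name, idx in spec}
    json_path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    return json_path


def read_layout(json_path: str | Path) -> ChannelLayout:
    """Read a channel layout: JSON list of ``{name, x, y, roi?}`` records."""
    json_path = Path(json_path)
    raw = json.loads(json_path.read_text(encoding="utf-8"))
    if not isinstance(raw, list):
        raise FormatError(f"{json_path}: expected a JSON list of channel records")
    names, xs, ys, rois = [], [], [], []
    for i, rec in enumerate(raw):
        for key in ("name", "x", "y"):
            if key not in rec:
                raise FormatError(f"{json_path}: record {i} missing {key!r}")
        names.append(str(rec["name"]))
        xs.append(float(rec["x"]))
        ys.append(float(rec["y"]))
        rois.append(rec.get("roi"))
    has_roi = any(r is not None for r in rois)
    if has_roi and any(r is None for r in rois):
        missing = [n for n, r in zip(names, rois) if r is None]
        raise ValidationError(f"roi: channels without ROI assignment: {missing}")
    return ChannelLayout(
        names=names,
        pos=np.column_stack([xs, ys]),
        roi=[str(r) for r in rois] if has_roi else None,
    )


def write_layout(layout: ChannelLayout, json_path: str | Path) -> Path:
    json_path = Path(json_path)
    records = []
    for i, name in enumerate(layout.names):
        rec = {"name": name, "x": float(layout.pos[i, 0]), "y": float(layout.pos[i, 1])}
        if layout.roi is not None:
            rec["roi"] = layout.roi[i]
        records.append(rec)
    json_path.write_text(json.dumps(records, indent=1) + "\n", encoding="utf-8")
    return json_path
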
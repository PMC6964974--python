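"""Shared domain containers for epoched trial data, feature matrices and groups.

The containers are thin, validated wrappers around numpy arrays.  They hold
exactly the information the decoding-and-interpretation pipeline needs:

* :class:`TrialEpochs` — epoched multichannel recordings (trial x channel x
  sample) with condition labels and a 2-D channel layout;
* :class:`FeatureMatrix` — a trials x predictors table with per-predictor
  metadata (channel name, integer frequency in Hz);
* :class:`GroupSpec` — named sets of predictor column indices (frequency
  bands, regions of interest, or arbitrary user-defined groups);
* :class:`ChannelLayout` — channel names, planar positions and optional
  region-of-interest assignment.

All indices are 0-based half-open, the numpy convention.  Validation happens
eagerly in ``__post_init__``; malformed inputs raise :class:`ValidationError`
naming the offending field — never a silent coercion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "ValidationError",
    "TrialEpochs",
    "FeatureMatrix",
    "PredictorMeta",
    "GroupSpec",
    "ChannelLayout",
    "PredictiveModel",
    "ModelFactory",
]


class ValidationError(ValueError):
    """A container invariant was violated; the message names the field."""


@runtime_checkable
class PredictiveModel(Protocol):
    """The minimal contract a fitted classifier must satisfy.

    The reliance engine treats the model as a black box: it only ever calls
    ``predict`` on held-out data.  Any scikit-learn classifier satisfies this
    after ``fit``.
    """

    def predict(self, X) -> np.ndarray: ...


@runtime_checkable
class ModelFactory(Protocol):
    """A zero-argument callable producing a fresh unfitted estimator.

    Estimators must expose ``fit(X, y)`` and, once fitted, ``predict(X)``.
    """

    def __call__(self) -> object: ...


def _as_array(x, name: str, dtype=None) -> np.ndarray:
    try:
        arr = np.asarray(x) if dtype is None else np.asarray(x, dtype=dtype)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name}: cannot interpret as array ({exc})") from exc
    return arr


@dataclass
class ChannelLayout:
    """Channel names, 2-D planar positions, optional ROI assignment.

    ROI membership is configuration, not something the package hard-codes:
    electrode-to-region tables differ between montages and studies.
    """

    names: list[str]
    pos: np.ndarray  # (n_channels, 2)
    roi: list[str] | None = None  # per-channel ROI label, optional

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        if len(set(self.names)) != len(self.names):
            raise ValidationError("names: duplicate channel names")
        self.pos = _as_array(self.pos, "pos", dtype=float)
        if self.pos.ndim != 2 or self.pos.shape[1] != 2:
            raise ValidationError(
                f"pos: expected (n_channels, 2), got shape {self.pos.shape}"
            )
        if self.pos.shape[0] != len(self.names):
            raise ValidationError(
                f"pos: {self.pos.shape[0]} rows but {len(self.names)} channel names"
            )
        if not np.all(np.isfinite(self.pos)):
            raise ValidationError("pos: positions must be finite")
        if self.roi is not None:
            self.roi = [str(r) for r in self.roi]
            if len(self.roi) != len(self.names):
                raise ValidationError(
                    f"roi: {len(self.roi)} labels but {len(self.names)} channels"
                )

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def roi_of(self, channel_name: str) -> str:
        """ROI label of a channel; raises if no ROI table or unknown channel."""
        if self.roi is None:
            raise ValidationError("roi: layout carries no ROI assignment")
        try:
            return self.roi[self.names.index(channel_name)]
        except ValueError:
            raise ValidationError(f"roi: unknown channel {channel_name!r}") from None


@dataclass
class TrialEpochs:
    """Epoched recordings: ``data[trial, channel, sample]`` plus metadata.

    Values are in arbitrary (microvolt-like) units.  ``labels`` are opaque
    integer condition codes; no ordinal structure is assumed.
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    srate: float
    channel_names: list[str]
    channel_pos: np.ndarray  # (n_channels, 2)
    labels: np.ndarray  # (n_trials,) small non-negative ints
    session_id: np.ndarray | None = None
    block_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = _as_array(self.data, "data", dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data: expected 3 axes (trial, channel, sample), got {self.data.ndim}"
            )
        self.srate = float(self.srate)
        if not self.srate > 0:
            raise ValidationError(f"srate: must be positive, got {self.srate}")
        self.channel_names = [str(n) for n in self.channel_names]
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel_names: duplicates present")
        self.channel_pos = _as_array(self.channel_pos, "channel_pos", dtype=float)
        if self.channel_pos.shape != (len(self.channel_names), 2):
            raise ValidationError(
                "channel_pos: expected shape "
                f"({len(self.channel_names)}, 2), got {self.channel_pos.shape}"
            )
        self.labels = _as_array(self.labels, "labels")
        if self.labels.ndim != 1:
            raise ValidationError("labels: expected a 1-D vector")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64, copy=True)
            if not np.array_equal(as_int, self.labels):
                raise ValidationError("labels: must be integer condition codes")
            self.labels = as_int
        if np.any(self.labels < 0):
            raise ValidationError("labels: negative condition code")
        n_trials, n_channels, _ = self.data.shape
        if len(self.labels) != n_trials:
            raise ValidationError(
                f"labels: length {len(self.labels)} != {n_trials} trials in data"
            )
        if n_channels != len(self.channel_names):
            raise ValidationError(
                f"channel_names: {len(self.channel_names)} names but data has "
                f"{n_channels} channels"
            )
        for name, attr in (("session_id", self.session_id), ("block_id", self.block_id)):
            if attr is not None:
                arr = _as_array(attr, name).astype(np.int64)
                if arr.shape != (n_trials,):
                    raise ValidationError(
                        f"{name}: expected shape ({n_trials},), got {arr.shape}"
                    )
                setattr(self, name, arr)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def layout(self, roi: list[str] | None = None) -> ChannelLayout:
        return ChannelLayout(names=self.channel_names, pos=self.channel_pos, roi=roi)


@dataclass(frozen=True)
class PredictorMeta:
    """Per-predictor annotation: source channel and integer frequency (Hz).

    ``frequency_hz`` is ``None`` for non-spectral predictors, in which case
    ``tag`` carries a free-form description.
    """

    channel_name: str
    frequency_hz: int | None = None
    tag: str | None = None

    def __post_init__(self) -> None:
        if self.frequency_hz is not None and self.frequency_hz <= 0:
            raise ValidationError(
                f"frequency_hz: must be a positive integer, got {self.frequency_hz}"
            )


@dataclass
class FeatureMatrix:
    """Trials x predictors design matrix ``X`` with labels ``y`` and metadata."""

    X: np.ndarray  # (n_trials, n_predictors)
    y: np.ndarray  # (n_trials,)
    meta: list[PredictorMeta]

    def __post_init__(self) -> None:
        self.X = _as_array(self.X, "X", dtype=float)
        if self.X.ndim != 2:
            raise ValidationError(f"X: expected 2 axes, got {self.X.ndim}")
        self.y = _as_array(self.y, "y")
        if self.y.ndim != 1:
            raise ValidationError("y: expected a 1-D label vector")
        if not np.issubdtype(self.y.dtype, np.integer):
            as_int = self.y.astype(np.int64, copy=True)
            if not np.array_equal(as_int, self.y):
                raise ValidationError("y: labels must be integers")
            self.y = as_int
        if self.X.shape[0] != len(self.y):
            raise ValidationError(
                f"y: length {len(self.y)} != {self.X.shape[0]} rows of X"
            )
        if self.X.shape[1] != len(self.meta):
            raise ValidationError(
                f"meta: {len(self.meta)} records but X has {self.X.shape[1]} columns"
            )

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.y))

    def subset_columns(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            X=self.X[:, idx], y=self.y.copy(), meta=[self.meta[j] for j in idx]
        )


@dataclass
class GroupSpec:
    """Named, possibly overlapping groups of 0-based predictor indices.

    Bands and ROIs overlap by construction (each spectral predictor belongs to
    one band and one ROI); every group's reliance is evaluated independently,
    so overlap is permitted.
    """

    groups: dict[str, np.ndarray]  # name -> sorted unique index array
    kinds: dict[str, str] = field(default_factory=dict)  # band | roi | custom
    n_predictors: int | None = None  # if known, bound for index validation

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("groups: at least one group required")
        clean: dict[str, np.ndarray] = {}
        for name, idx in self.groups.items():
            arr = np.unique(_as_array(idx, f"groups[{name!r}]").astype(np.int64))
            if arr.size == 0:
                raise ValidationError(f"groups[{name!r}]: group is empty")
            if arr[0] < 0:
                raise ValidationError(f"groups[{name!r}]: negative index {arr[0]}")
            if self.n_predictors is not None and arr[-1] >= self.n_predictors:
                raise ValidationError(
                    f"groups[{name!r}]: index {arr[-1]} out of range "
                    f"(p = {self.n_predictors})"
                )
            clean[str(name)] = arr
        self.groups = clean
        self.kinds = {str(k): str(v) for k, v in self.kinds.items()}
        for name in self.kinds:
            if name not in self.groups:
                raise ValidationError(f"kinds: unknown group {name!r}")

    def __iter__(self):
        return iter(self.groups.items())

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    def kind(self, name: str) -> str:
        return self.kinds.get(name, "custom")

    def sizes(self) -> dict[str, int]:
        return {name: int(idx.size) for name, idx in self.groups.items()}
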
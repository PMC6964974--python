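"""Synthetic data: Sternberg-style EEG epochs and grouped tabular fixtures.

Two generators make every pipeline stage testable without real recordings.

:func:`simulate_subject` emulates the retention interval of a Sternberg
working-memory experiment: three balanced memory-load conditions (1, 4 or 7
digits), 3 sessions x 6 blocks x 54 trials = 972 trials, a 122-channel
hexagonal montage, 3 s epochs at 512 Hz.  Each trial is 1/f (colored) noise
on every channel plus a band-limited oscillation at a subject-specific peak
frequency on the channels of the affected regions of interest.  Oscillation
amplitude is linear in load rank, ``base * (1 + slope * rank)`` with rank 0,
1, 2 for loads 1, 4, 7 — the simplest monotone model of amplitude scaling
with load.  The slope is signed: amplitude may rise with load in one subject
and fall in another, mimicking the inter-individual heterogeneity seen in
real cohorts.  Only the retention epoch is simulated — no probe or response
phases, no ocular or cardiac artifacts (inputs are assumed cleaned).

:func:`simulate_grouped_tabular` plants class-conditional Gaussian signal in
chosen predictor groups of a generic feature matrix — the minimal fixture
for exercising the reliance machinery directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import ChannelLayout, FeatureMatrix, GroupSpec, PredictorMeta, TrialEpochs, ValidationError

__all__ = [
    "SimulationConfig",
    "hex_layout",
    "simulate_subject",
    "simulate_grouped_tabular",
    "shuffle_labels",
]

ROI_NAMES = [
    f"{side}_{region}"
    for region in ("frontal", "central", "occipital")
    for side in ("left", "central", "right")
]


def hex_layout(n_channels: int = 122, pitch: float = 1.0) -> ChannelLayout:
    """Equidistant hexagonal montage with a 3 x 3 spatial ROI partition.

    Points grow ring by ring around the vertex; the ``n_channels`` closest to
    the center are retained (the default keeps 122 — a 128-electrode cap
    minus six ear-adjacent channels).  ROIs are assigned by tercile splits of
    the y coordinate (frontal / central / occipital, front = +y) and the x
    coordinate (left / central / right), giving the conventional nine
    regions.
    """
    if n_channels < 9:
        raise ValidationError(f"n_channels: need >= 9 for a 9-ROI layout, got {n_channels}")
    # Axial hex coordinates out to a sufficient ring count.
    rings = 1
    while 1 + 3 * rings * (rings + 1) < n_channels:
        rings += 1
    pts = []
    for q in range(-rings, rings + 1):
        for r in range(max(-rings, -q - rings), min(rings, -q + rings) + 1):
            x = pitch * (q + r / 2.0)
            y = pitch * (np.sqrt(3) / 2.0) * r
            pts.append((x, y))
    pts = np.asarray(pts)
    order = np.lexsort((np.arctan2(pts[:, 1], pts[:, 0]), np.linalg.norm(pts, axis=1)))
    pos = pts[order[:n_channels]]
    names = [f"E{i + 1:03d}" for i in range(n_channels)]

    def tercile(v: np.ndarray) -> np.ndarray:
        lo, hi = np.quantile(v, [1 / 3, 2 / 3])
        return np.digitize(v, [lo, hi], right=True)  # 0, 1, 2

    xs, ys = tercile(pos[:, 0]), tercile(pos[:, 1])
    side = np.array(["left", "central", "right"])[xs]
    region = np.array(["occipital", "central", "frontal"])[ys]  # +y is anterior
    roi = [f"{s}_{r}" for s, r in zip(side, region)]
    return ChannelLayout(names=names, pos=pos, roi=roi)


@dataclass
class SimulationConfig:
    """Design and signal parameters of one simulated subject.

    Defaults reproduce the Sternberg design: 3 sessions x 6 blocks x 54
    trials (18 per load per block), loads 1/4/7, 122 channels, 3 s retention
    epochs at 512 Hz.  The oscillatory effect lives in ``band`` on the
    channels of ``affected_rois``; ``slope`` scales amplitude with load rank
    and may be negative.
    """

    n_channels: int = 122
    srate: float = 512.0
    epoch_s: float = 3.0
    sessions: int = 3
    blocks_per_session: int = 6
    trials_per_block: int = 54
    loads: tuple[int, ...] = (1, 4, 7)
    band: tuple[int, int] = (8, 12)
    peak_freq_hz: int | None = None  # None: drawn per subject within band
    affected_rois: tuple[str, ...] = ("central_occipital",)
    base_amplitude: float = 0.6
    slope: float = 0.75
    amp_jitter: float = 0.4  # lognormal sigma of trial-to-trial amplitude
    noise_exponent: float = 1.0
    white_floor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.band[0] <= self.band[1] <= 40):
            raise ValidationError(f"band: {self.band} outside [1, 40]")
        if len(self.affected_rois) == 0:
            raise ValidationError("affected_rois: empty ROI set")
        if self.trials_per_block % len(self.loads) != 0:
            raise ValidationError(
                f"trials_per_block: {self.trials_per_block} not divisible by "
                f"{len(self.loads)} loads"
            )

    @property
    def n_trials(self) -> int:
        return self.sessions * self.blocks_per_session * self.trials_per_block

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _colored_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
    exponent: float, srate: float,
) -> np.ndarray:
    """1/f^exponent noise along the last axis via spectral shaping."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    shape_f = np.ones_like(f)
    shape_f[1:] = f[1:] ** (-exponent / 2.0)
    shape_f[0] = 0.0  # no DC
    return np.fft.irfft(spec * shape_f, n=n_samples, axis=-1)


def simulate_subject(
    cfg: SimulationConfig, subject_idx: int = 0, layout: ChannelLayout | None = None
) -> TrialEpochs:
    """Simulate one subject's epoched retention-interval recordings.

    Per trial, every channel carries colored noise (plus a white floor); the
    affected-ROI channels additionally carry a sinusoid at the subject's
    peak frequency with a random phase, whose amplitude is
    ``base * (1 + slope * load_rank)`` (clipped at zero) scaled by unit-mean
    lognormal trial-to-trial jitter.  Trials are
    balanced over loads within each block and shuffled.  Each
    ``subject_idx`` under one master seed yields a distinct realization.
    """
    if layout is None:
        layout = hex_layout(cfg.n_channels)
    unknown = set(cfg.affected_rois) - set(layout.roi or [])
    if unknown:
        raise ValidationError(f"affected_rois: not in layout: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, subject_idx)))
    peak = (
        cfg.peak_freq_hz
        if cfg.peak_freq_hz is not None
        else int(rng.integers(cfg.band[0], cfg.band[1] + 1))
    )
    n_samples = int(round(cfg.epoch_s * cfg.srate))
    n_trials = cfg.n_trials
    per_load = cfg.trials_per_block // len(cfg.loads)

    labels = np.empty(n_trials, dtype=np.int64)
    session_id = np.empty(n_trials, dtype=np.int64)
    block_id = np.empty(n_trials, dtype=np.int64)
    t = 0
    for s in range(cfg.sessions):
        for b in range(cfg.blocks_per_session):
            block = np.repeat(cfg.loads, per_load)
            rng.shuffle(block)
            sl = slice(t, t + cfg.trials_per_block)
            labels[sl] = block
            session_id[sl] = s
            block_id[sl] = b
            t += cfg.trials_per_block

    affected = np.array(
        [r in cfg.affected_rois for r in layout.roi], dtype=bool
    )
    rank = np.searchsorted(np.sort(cfg.loads), labels).astype(float)
    amp = np.maximum(cfg.base_amplitude * (1.0 + cfg.slope * rank), 0.0)
    if cfg.amp_jitter > 0:  # lognormal, unit mean: realistic trial variability
        sig = cfg.amp_jitter
        amp = amp * rng.lognormal(-0.5 * sig**2, sig, size=n_trials)
    tgrid = np.arange(n_samples) / cfg.srate

    data = np.empty((n_trials, cfg.n_channels, n_samples))
    chunk = 64
    for start in range(0, n_trials, chunk):
        sl = slice(start, min(start + chunk, n_trials))
        nb = sl.stop - sl.start
        block = _colored_noise(
            rng, (nb, cfg.n_channels), n_samples, cfg.noise_exponent, cfg.srate
        )
        block += cfg.white_floor * rng.standard_normal(block.shape)
        phase = rng.uniform(0.0, 2 * np.pi, size=nb)
        osc = np.sin(2 * np.pi * peak * tgrid[None, :] + phase[:, None])
        block[:, affected, :] += (amp[sl, None] * osc)[:, None, :]
        data[sl] = block

    return TrialEpochs(
        data=data,
        srate=cfg.srate,
        channel_names=layout.names,
        channel_pos=layout.pos,
        labels=labels,
        session_id=session_id,
        block_id=block_id,
    )


def simulate_grouped_tabular(
    n: int,
    group_sizes: list[int],
    informative: set[str] | list[str],
    effect: float,
    within_group_corr: float = 0.0,
    n_classes: int = 3,
    seed: int = 0,
) -> tuple[FeatureMatrix, GroupSpec]:
    """Generic grouped features with class-conditional Gaussian signal.

    Groups are named ``g0, g1, ...`` with the given sizes.  Columns of
    informative groups have their mean shifted by ``effect * class_rank``;
    all other columns are pure noise.  ``within_group_corr`` induces
    equicorrelation inside each group via a shared per-trial factor.
    Classes are balanced (surplus trials go to the lowest class codes) and
    trial order is shuffled.
    """
    if effect < 0:
        raise ValidationError(f"effect: must be >= 0, got {effect}")
    if not 0 <= within_group_corr < 1:
        raise ValidationError(
            f"within_group_corr: must be in [0, 1), got {within_group_corr}"
        )
    names = [f"g{i}" for i in range(len(group_sizes))]
    informative = set(informative)
    unknown = informative - set(names)
    if unknown:
        raise ValidationError(f"informative: unknown group(s) {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    base, rem = divmod(n, n_classes)
    y = np.concatenate(
        [np.full(base + (1 if c < rem else 0), c, dtype=np.int64)
         for c in range(n_classes)]
    )
    rng.shuffle(y)

    cols, meta = [], []
    groups: dict[str, np.ndarray] = {}
    j = 0
    rho = within_group_corr
    for name, size in zip(names, group_sizes):
        if size < 1:
            raise ValidationError(f"group_sizes: group {name} has size {size}")
        shared = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, size))
        block = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
        if name in informative:
            block = block + effect * y[:, None].astype(float)
        cols.append(block)
        groups[name] = np.arange(j, j + size)
        meta.extend(
            PredictorMeta(channel_name=f"v{j + i}", tag=name) for i in range(size)
        )
        j += size
    fm = FeatureMatrix(X=np.hstack(cols), y=y, meta=meta)
    spec = GroupSpec(
        groups=groups, kinds={nm: "custom" for nm in names}, n_predictors=j
    )
    return fm, spec


def shuffle_labels(fm: FeatureMatrix, seed: int = 0) -> FeatureMatrix:
    """Permute labels independently of the features (null-calibration fixture)."""
    rng = np.random.default_rng(seed)
    return FeatureMatrix(X=fm.X.copy(), y=rng.permutation(fm.y), meta=list(fm.meta))
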
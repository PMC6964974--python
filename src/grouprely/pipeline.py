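"""End-to-end orchestration: simulate -> spectra -> reliance -> cluster test.

A :class:`RunConfig` (plain dataclass, YAML-serializable) fully determines a
run; replaying the same config and inputs reproduces every output table
byte-for-byte.  Each stage logs to stderr with a stage-scoped prefix and its
wall time; outputs are listed in a JSON manifest.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import build_adjacency, cluster_permutation_test
from .io import write_epochs, write_feature_table, write_group_spec, write_layout
from .reliance import (
    RelianceResult,
    cross_validated_reliance,
    group_only_accuracy,
    leave_one_subject_out,
    random_forest_factory,
    svm_factory,
)
from .spectral import DEFAULT_BANDS, BandDefinition, band_groups, power_spectrum, roi_groups
from .synthetic import SimulationConfig, hex_layout, simulate_subject
from .types import GroupSpec, ValidationError

__all__ = ["RunConfig", "run_pipeline", "summarize", "make_factory"]

log = logging.getLogger("grouprely")


@dataclass
class RunConfig:
    """Everything needed to replay a pipeline run."""

    out_dir: str = "grouprely_out"
    n_subjects: int = 1
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    freqs: tuple[int, int] = (1, 40)
    bands: list[dict] | None = None  # [{name, lo_hz, hi_hz}]; default canon bands
    model: str = "rf"  # rf | svm
    n_trees: int = 5000
    svm_c: float = 1.0
    k: int = 10
    n_perm: int = 10
    seed: int = 0
    mode: str = "ratio"
    normalize: bool = True
    permutation: str = "joint"
    group_only: bool = False
    loso: bool = False
    cluster_test: bool = True
    cluster_band: tuple[int, int] = (8, 12)
    cluster_n_perm: int = 1000
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    max_dist: float = 1.1
    write_features: bool = False  # full feature TSVs are large; opt in

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"config: unknown key(s) {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("freqs", "cluster_band"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")
        return path


def make_factory(cfg: RunConfig):
    if cfg.model == "rf":
        return random_forest_factory(n_trees=cfg.n_trees), f"rf({cfg.n_trees} trees)"
    if cfg.model == "svm":
        return svm_factory(C=cfg.svm_c), f"svm(rbf, C={cfg.svm_c})"
    raise ValidationError(f"model: expected rf|svm, got {cfg.model!r}")


def _bands(cfg: RunConfig) -> tuple[BandDefinition, ...]:
    if cfg.bands is None:
        return DEFAULT_BANDS
    return tuple(BandDefinition(b["name"], int(b["lo_hz"]), int(b["hi_hz"]))
                 for b in cfg.bands)


class _Stage:
    """Context manager logging a stage's start, end and wall time."""

    def __init__(self, name: str, timings: dict):
        self.name, self.timings = name, timings

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("[%s] start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is not None:
            log.error("[%s] FAILED after %.1fs: %s", self.name, dt, exc)
            return False
        self.timings[self.name] = round(dt, 3)
        log.info("[%s] done in %.1fs", self.name, dt)
        return False


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict.

    Stages: simulate each subject, extract spectral predictors, build
    band/ROI groups, estimate grouped reliance (optionally group-only
    accuracies and leave-one-subject-out decoding), run the cluster
    permutation test on the configured band, and summarize across subjects.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "version": __version__,
        "numpy": np.__version__,
        "config": asdict(cfg),
        "outputs": {},
    }
    factory, model_desc = make_factory(cfg)
    sim_cfg = SimulationConfig(**{"seed": cfg.seed, **cfg.simulation})
    layout = hex_layout(sim_cfg.n_channels)
    manifest["outputs"]["layout"] = str(write_layout(layout, out / "layout.json"))

    freqs = range(cfg.freqs[0], cfg.freqs[1] + 1)
    per_subject_results: list[RelianceResult] = []
    per_subject_fms = []
    group_only_rows = []
    cluster_paths = []

    for s in range(cfg.n_subjects):
        tag = f"subj{s:02d}"
        with _Stage(f"simulate:{tag}", timings):
            epochs = simulate_subject(sim_cfg, subject_idx=s, layout=layout)
            manifest["outputs"][f"epochs_{tag}"] = str(
                write_epochs(epochs, out / f"{tag}.h5")
            )
        with _Stage(f"spectra:{tag}", timings):
            fm = power_spectrum(epochs, freqs)
            if cfg.write_features:
                tsv, meta = write_feature_table(
                    fm, out / f"{tag}_features.tsv", out / f"{tag}_features.json"
                )
                manifest["outputs"][f"features_{tag}"] = str(tsv)
                manifest["outputs"][f"features_meta_{tag}"] = str(meta)
        groups = _merge_groups(
            band_groups(fm.meta, _bands(cfg)), roi_groups(fm.meta, layout)
        )
        if s == 0:
            manifest["outputs"]["groups"] = str(
                write_group_spec(groups, out / "groups.json")
            )
        with _Stage(f"reliance:{tag}", timings):
            res = cross_validated_reliance(
                factory, fm, groups, k=cfg.k, n_perm=cfg.n_perm,
                seed=cfg.seed + s, normalize=cfg.normalize, mode=cfg.mode,
                permutation=cfg.permutation, model_name=model_desc,
            )
            path = out / f"{tag}_reliance.json"
            path.write_text(json.dumps(res.to_dict(), indent=1), encoding="utf-8")
            manifest["outputs"][f"reliance_{tag}"] = str(path)
            per_subject_results.append(res)
        if cfg.group_only:
            with _Stage(f"group-only:{tag}", timings):
                accs = group_only_accuracy(
                    factory, fm, groups, k=cfg.k, seed=cfg.seed + s
                )
                group_only_rows.append({"subject": s, **accs})
        if cfg.loso:
            per_subject_fms.append(fm)
        if cfg.cluster_test:
            with _Stage(f"cluster:{tag}", timings):
                lo, hi = cfg.cluster_band
                band_freqs = list(range(lo, hi + 1))
                n_fr = len(list(freqs))
                power = fm.X.reshape(fm.n_trials, len(layout.names), n_fr)
                fsel = [f - cfg.freqs[0] for f in band_freqs]
                adj = build_adjacency(layout, cfg.max_dist)
                cres = cluster_permutation_test(
                    power[:, :, fsel], fm.y, adj,
                    n_perm=cfg.cluster_n_perm, alpha=cfg.alpha,
                    cluster_alpha=cfg.cluster_alpha, seed=cfg.seed + s,
                    freqs_hz=band_freqs,
                )
                path = out / f"{tag}_clusters.json"
                path.write_text(json.dumps(cres.to_dict(), indent=1),
                                encoding="utf-8")
                manifest["outputs"][f"clusters_{tag}"] = str(path)
                cluster_paths.append(str(path))
                fmap = pd.DataFrame(
                    cres.stat_map.F, index=layout.names, columns=band_freqs
                )
                fpath = out / f"{tag}_fmap.tsv"
                fmap.to_csv(fpath, sep="\t", lineterminator="\n")
                manifest["outputs"][f"fmap_{tag}"] = str(fpath)

    with _Stage("summarize", timings):
        tables = summarize(per_subject_results)
        for name, df in tables.items():
            path = out / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False, lineterminator="\n")
            manifest["outputs"][name] = str(path)
        if group_only_rows:
            path = out / "group_only_accuracy.tsv"
            pd.DataFrame(group_only_rows).to_csv(
                path, sep="\t", index=False, lineterminator="\n"
            )
            manifest["outputs"]["group_only_accuracy"] = str(path)

    if cfg.loso and cfg.n_subjects >= 2:
        with _Stage("loso", timings):
            accs, mean = leave_one_subject_out(factory, per_subject_fms,
                                               seed=cfg.seed)
            path = out / "loso_accuracy.tsv"
            df = pd.DataFrame(
                {"subject": list(range(len(accs))) + ["mean"],
                 "accuracy": accs + [mean]}
            )
            df.to_csv(path, sep="\t", index=False, lineterminator="\n")
            manifest["outputs"]["loso_accuracy"] = str(path)

    manifest["timings_s"] = timings
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    log.info("manifest written to %s", mpath)
    return manifest


def _merge_groups(a: GroupSpec, b: GroupSpec) -> GroupSpec:
    groups = {**a.groups, **b.groups}
    kinds = {**a.kinds, **b.kinds}
    if len(groups) != len(a) + len(b):
        dup = sorted(set(a.groups) & set(b.groups))
        raise ValidationError(f"groups: duplicate group names {dup}")
    return GroupSpec(groups=groups, kinds=kinds, n_predictors=a.n_predictors)


def summarize(results: list[RelianceResult]) -> dict[str, pd.DataFrame]:
    """Across-subject summary tables from per-subject reliance results.

    Returns ``reliance_by_subject`` (one row per subject x group),
    ``reliance_summary`` (per-group mean / quartiles across subjects),
    ``top_groups`` (each subject's highest-reliance group) and
    ``accuracy`` (per-subject mean CV accuracy with the chance level).
    """
    if not results:
        raise ValidationError("results: need at least one subject")
    rows = [
        {"subject": s, "group": g, "mr": mr}
        for s, res in enumerate(results)
        for g, mr in res.group_means.items()
    ]
    by_subject = pd.DataFrame(rows)
    agg = (
        by_subject.groupby("group")["mr"]
        .agg(mean="mean", median="median",
             q1=lambda v: v.quantile(0.25), q3=lambda v: v.quantile(0.75))
        .reset_index()
        .sort_values("mean", ascending=False, kind="stable")
    )
    top = (
        by_subject.loc[by_subject.groupby("subject")["mr"].idxmax()]
        .rename(columns={"group": "top_group", "mr": "top_mr"})
        .reset_index(drop=True)
    )
    acc = pd.DataFrame(
        {
            "subject": range(len(results)),
            "mean_accuracy": [r.mean_accuracy for r in results],
            "chance_level": [
                1.0 / r.settings.get("n_classes", 3) for r in results
            ],
        }
    )
    return {
        "reliance_by_subject": by_subject,
        "reliance_summary": agg,
        "top_groups": top,
        "accuracy": acc,
    }
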
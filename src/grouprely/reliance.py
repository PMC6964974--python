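"""Grouped model reliance under stratified shuffled k-fold cross-validation.

Model reliance measures how much a *fitted* classifier depends on a group of
predictor columns ``J``: the columns are randomly permuted on a held-out
validation fold, destroying their association with the labels while leaving
their marginal distribution intact, and the resulting accuracy drop is turned
into a score.  With baseline accuracy ``ACC_bl`` and post-permutation accuracy
``ACC_perm(J)``, the ratio-mode score normalized by group size is

    MR(X_J) = (1 / |J|) * ((1 - ACC_perm(J)) / (1 - ACC_bl) - 1)

i.e. the ratio of permuted to baseline error, minus one, divided by the number
of variables in the group so that differently sized groups (a 2440-column
gamma band vs. a 610-column alpha band) are comparable.  Difference mode
replaces the error ratio by the error difference.  The model is never
re-trained: permutation happens on the validation fold only, and prediction is
repeated with the already-fitted model.

Scores are averaged over ``n_perm`` random permutations within each fold and
then over the ``k`` folds (a plain Monte-Carlo estimate; enumerating all
permutations is prohibitive, a single one is too noisy).  Negative values can
arise by chance; large consistent negative values mean permutation *helps*.

Two permutation schemes are provided.  ``joint`` (default) applies one row
permutation to all columns of the group simultaneously, preserving the
within-group covariance — the grouped-permutation-importance convention.
``independent`` permutes each column separately.

Numerical note: the size-normalized score is the canonical per-record value;
the un-normalized score is obtained from it by multiplying back with ``|J|``,
so the pair is exactly consistent (``mr_unnormalized == mr_normalized * |J|``
bit-for-bit).  The derived value agrees with direct evaluation of the
un-normalized formula to within one ulp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .types import FeatureMatrix, GroupSpec, ValidationError

__all__ = [
    "RelianceRecord",
    "RelianceResult",
    "DegenerateBaselineWarning",
    "reliance_value",
    "permute_group",
    "group_reliance",
    "stratified_folds",
    "cv_accuracy",
    "cross_validated_reliance",
    "group_only_accuracy",
    "leave_one_subject_out",
    "random_forest_factory",
    "svm_factory",
]

#: Forest size used in the original analyses; tests use far fewer for speed.
DEFAULT_N_TREES = 5000


class DegenerateBaselineWarning(UserWarning):
    """Perfect baseline accuracy makes the error ratio undefined."""


@dataclass(frozen=True)
class RelianceRecord:
    """One (group, fold, permutation) reliance measurement."""

    group: str
    fold: int
    perm: int
    acc_bl: float
    acc_perm: float
    mr: float
    degenerate: bool = False


@dataclass
class RelianceResult:
    """All reliance records of a cross-validated run plus aggregates.

    ``group_means`` is the two-stage average: permutations within a fold
    first, then folds.  ``settings`` fully reproduce the run given the same
    inputs and factory.
    """

    records: list[RelianceRecord]
    group_means: dict[str, float]
    fold_accuracies: list[float]
    mean_accuracy: float
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "settings": self.settings,
            "mean_accuracy": self.mean_accuracy,
            "fold_accuracies": list(self.fold_accuracies),
            "group_means": dict(self.group_means),
            "records": [
                {
                    "group": r.group,
                    "fold": r.fold,
                    "perm": r.perm,
                    "acc_bl": r.acc_bl,
                    "acc_perm": r.acc_perm,
                    "mr": r.mr,
                    "degenerate": r.degenerate,
                }
                for r in self.records
            ],
        }


def reliance_value(
    acc_bl: float,
    acc_perm: float,
    group_size: int,
    normalize: bool = True,
    mode: str = "ratio",
) -> tuple[float, bool]:
    """Turn baseline and permuted accuracy into a reliance score.

    Returns ``(mr, degenerate)``.  In ratio mode a perfect baseline
    (``acc_bl == 1``) leaves the error ratio undefined; the difference-mode
    value is returned instead, flagged degenerate, with a warning — never a
    silent infinity.
    """
    if mode not in ("ratio", "difference"):
        raise ValidationError(f"mode: expected ratio|difference, got {mode!r}")
    if group_size < 1:
        raise ValidationError(f"group_size: must be >= 1, got {group_size}")
    err_bl = 1.0 - acc_bl
    err_perm = 1.0 - acc_perm
    degenerate = False
    if mode == "ratio":
        if err_bl == 0.0:
            warnings.warn(
                "baseline accuracy is 1.0: error ratio undefined, "
                "falling back to the difference-mode value",
                DegenerateBaselineWarning,
                stacklevel=2,
            )
            degenerate = True
            raw = err_perm - err_bl
        else:
            raw = err_perm / err_bl - 1.0
    else:
        raw = err_perm - err_bl
    normalized = raw / group_size
    return (normalized if normalize else normalized * group_size), degenerate


def permute_group(
    X: np.ndarray,
    J: Sequence[int] | np.ndarray,
    rng: np.random.Generator,
    mode: str = "joint",
) -> np.ndarray:
    """Return a copy of ``X`` with the columns in ``J`` row-permuted.

    ``joint`` applies one row permutation to all columns of the group at once
    (within-group structure preserved); ``independent`` draws a separate
    permutation per column.  Columns outside ``J`` are untouched and the
    input is never mutated.
    """
    J = np.asarray(J, dtype=np.int64)
    if J.size == 0:
        raise ValidationError("J: group index set is empty")
    if J.min() < 0 or J.max() >= X.shape[1]:
        raise ValidationError(
            f"J: indices out of range for {X.shape[1]} columns"
        )
    if mode not in ("joint", "independent"):
        raise ValidationError(f"mode: expected joint|independent, got {mode!r}")
    out = X.copy()
    n = X.shape[0]
    if mode == "joint":
        order = rng.permutation(n)
        out[:, J] = X[np.ix_(order, J)]
    else:
        for j in J:
            out[:, j] = X[rng.permutation(n), j]
    return out


def group_reliance(
    model,
    Xv: np.ndarray,
    yv: np.ndarray,
    J: Sequence[int] | np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    normalize: bool = True,
    mode_def: str = "ratio",
    permutation: str = "joint",
    acc_bl: float | None = None,
    group: str = "",
    fold: int = 0,
) -> list[RelianceRecord]:
    """Per-permutation reliance records for one group on one validation fold.

    The model must already be fitted; it is only asked to predict.  The
    baseline accuracy does not depend on ``J``, so a precomputed ``acc_bl``
    may be passed in and reused across groups and permutations of the fold.
    """
    J = np.asarray(J, dtype=np.int64)
    if acc_bl is None:
        acc_bl = float(np.mean(model.predict(Xv) == yv))
    records = []
    for p in range(n_perm):
        Xp = permute_group(Xv, J, rng, mode=permutation)
        acc_perm = float(np.mean(model.predict(Xp) == yv))
        mr, degenerate = reliance_value(
            acc_bl, acc_perm, int(J.size), normalize=normalize, mode=mode_def
        )
        records.append(
            RelianceRecord(
                group=group, fold=fold, perm=p,
                acc_bl=acc_bl, acc_perm=acc_perm, mr=mr, degenerate=degenerate,
            )
        )
    return records


def stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded, shuffled, stratified fold assignment.

    Each class's trials are shuffled and dealt round-robin, so per-fold class
    counts differ by at most one trial and surplus trials land on the
    lowest-indexed folds — a fixed tie-break for reproducibility.
    """
    y = np.asarray(y)
    if k < 2:
        raise ValidationError(f"k: need at least 2 folds, got {k}")
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < k]
    if too_small.size:
        raise ValidationError(
            f"y: class(es) {too_small.tolist()} have fewer than k={k} members"
        )
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in classes:
        idx = rng.permutation(np.flatnonzero(y == c))
        for pos, trial in enumerate(idx):
            folds[pos % k].append(int(trial))
    return [np.sort(np.asarray(f, dtype=np.int64)) for f in folds]


def _derive_streams(seed: int, k: int):
    """Folds, per-fold model seeds and a permutation RNG from one master seed."""
    ss = np.random.SeedSequence(seed)
    fold_ss, model_ss, perm_ss = ss.spawn(3)
    fold_rng = np.random.default_rng(fold_ss)
    model_seeds = np.random.default_rng(model_ss).integers(2**31, size=k)
    return fold_rng, model_seeds, np.random.default_rng(perm_ss)


def _seeded_model(factory: Callable[[], object], seed: int):
    """Instantiate a model; give it a derived seed if it wants one.

    Estimators constructed with ``random_state=None`` receive a seed derived
    from the master seed, so runs are bit-reproducible without the caller
    having to thread seeds through the factory.
    """
    model = factory()
    if getattr(model, "random_state", "missing") is None:
        model.random_state = int(seed)
    return model


def _fit_predict_folds(
    factory, X: np.ndarray, y: np.ndarray, k: int, seed: int
) -> tuple[list, list[np.ndarray], list[float], np.random.Generator]:
    """Shared CV loop: fitted models, validation folds, fold accuracies."""
    fold_rng, model_seeds, perm_rng = _derive_streams(seed, k)
    folds = stratified_folds(y, k, fold_rng)
    models, accs = [], []
    for i, val_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[val_idx] = False
        model = _seeded_model(factory, model_seeds[i])
        model.fit(X[train_mask], y[train_mask])
        accs.append(float(np.mean(model.predict(X[val_idx]) == y[val_idx])))
        models.append(model)
    return models, folds, accs, perm_rng


def cv_accuracy(
    factory, fm: FeatureMatrix, k: int = 10, seed: int = 0
) -> tuple[float, list[float]]:
    """Mean stratified shuffled k-fold CV accuracy (and per-fold values)."""
    _, _, accs, _ = _fit_predict_folds(factory, fm.X, fm.y, k, seed)
    return float(np.mean(accs)), accs


def cross_validated_reliance(
    factory,
    fm: FeatureMatrix,
    groups: GroupSpec,
    k: int = 10,
    n_perm: int = 10,
    seed: int = 0,
    normalize: bool = True,
    mode: str = "ratio",
    permutation: str = "joint",
    model_name: str | None = None,
) -> RelianceResult:
    """Grouped model reliance over a stratified shuffled k-fold CV.

    Per fold the model is fitted on the training part; the baseline accuracy
    is computed once on the validation part and reused for every group and
    permutation of that fold.  Per group, ``n_perm`` permutation records are
    collected; the reported per-group mean is the mean over permutations
    within each fold, then over folds.  Mean CV accuracy is reported
    alongside.
    """
    models, folds, fold_accs, perm_rng = _fit_predict_folds(
        factory, fm.X, fm.y, k, seed
    )
    records: list[RelianceRecord] = []
    for i, val_idx in enumerate(folds):
        Xv, yv = fm.X[val_idx], fm.y[val_idx]
        for name, J in groups:
            records.extend(
                group_reliance(
                    models[i], Xv, yv, J, n_perm, perm_rng,
                    normalize=normalize, mode_def=mode, permutation=permutation,
                    acc_bl=fold_accs[i], group=name, fold=i,
                )
            )
    group_means = _two_stage_means(records, groups.names, k)
    settings = {
        "k": k, "n_perm": n_perm, "seed": seed, "normalize": normalize,
        "mode": mode, "permutation": permutation,
        "n_classes": int(np.unique(fm.y).size),
        "model": model_name if model_name is not None else repr(factory()),
        "group_sizes": groups.sizes(),
    }
    return RelianceResult(
        records=records,
        group_means=group_means,
        fold_accuracies=fold_accs,
        mean_accuracy=float(np.mean(fold_accs)),
        settings=settings,
    )


def _two_stage_means(
    records: Iterable[RelianceRecord], names: list[str], k: int
) -> dict[str, float]:
    """Mean over permutations within each fold, then mean over folds."""
    by_group_fold: dict[tuple[str, int], list[float]] = {}
    for r in records:
        by_group_fold.setdefault((r.group, r.fold), []).append(r.mr)
    means = {}
    for name in names:
        fold_means = [np.mean(by_group_fold[(name, i)]) for i in range(k)]
        means[name] = float(np.mean(fold_means))
    return means


def group_only_accuracy(
    factory, fm: FeatureMatrix, groups: GroupSpec, k: int = 10, seed: int = 0
) -> dict[str, float]:
    """Mean CV accuracy of models trained and tested on each group alone.

    Complements reliance: a group with redundant information can show low
    reliance yet still decode well on its own.  Fold assignment and model
    seeding depend only on ``(y, k, seed)``, so a group containing all
    columns reproduces the standard CV accuracy for the same seed.
    """
    out = {}
    for name, J in groups:
        mean_acc, _ = cv_accuracy(factory, fm.subset_columns(J), k=k, seed=seed)
        out[name] = mean_acc
    return out


def leave_one_subject_out(
    factory, per_subject_fms: Sequence[FeatureMatrix], seed: int = 0
) -> tuple[list[float], float]:
    """Between-subject decoding: folds are given by individual subjects.

    For each subject the model is fitted on all other subjects' pooled trials
    and tested on that subject's trials.  Returns per-subject held-out
    accuracies and their mean.
    """
    if len(per_subject_fms) < 2:
        raise ValidationError("per_subject_fms: need at least 2 subjects")
    ref = per_subject_fms[0].meta
    for s, fm in enumerate(per_subject_fms[1:], start=1):
        if fm.meta != ref:
            raise ValidationError(
                f"per_subject_fms: subject {s} predictor metadata differs "
                "from subject 0"
            )
    model_seeds = np.random.default_rng(np.random.SeedSequence(seed)).integers(
        2**31, size=len(per_subject_fms)
    )
    accs = []
    for s, test_fm in enumerate(per_subject_fms):
        X_train = np.vstack(
            [fm.X for t, fm in enumerate(per_subject_fms) if t != s]
        )
        y_train = np.concatenate(
            [fm.y for t, fm in enumerate(per_subject_fms) if t != s]
        )
        model = _seeded_model(factory, model_seeds[s])
        model.fit(X_train, y_train)
        accs.append(float(np.mean(model.predict(test_fm.X) == test_fm.y)))
    return accs, float(np.mean(accs))


def random_forest_factory(
    n_trees: int = DEFAULT_N_TREES,
    random_state: int | None = None,
    n_jobs: int | None = None,
    **kwargs,
):
    """Factory for the default tree-ensemble model (5000 trees)."""

    def make() -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_trees, random_state=random_state, n_jobs=n_jobs,
            **kwargs,
        )

    return make


def svm_factory(C: float = 1.0, gamma: str | float = "scale", **kwargs):
    """Factory for the RBF-kernel support vector machine (C = 1)."""

    def make() -> SVC:
        return SVC(kernel="rbf", C=C, gamma=gamma, **kwargs)

    return make
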
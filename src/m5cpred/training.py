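"""RBF-SVM training, grid search and stratified 10-fold cross-validation.

The classifier follows the MATLAB ``fitcsvm`` convention: an RBF kernel
``K(x, y) = exp(-||x - y||^2 / s^2)`` parameterized by a *kernel scale* s
and a *box constraint* C, both searched over powers of two (C in 2^-5 ..
2^15, s in 2^-10 .. 2^6).  Internally s maps to scikit-learn's
``gamma = 1 / s^2``.

Features are z-scored per column with statistics from the training data
(zero-variance columns are dropped and recorded).  Inside cross-validation
the position-specific propensity matrices *and* the scaler are refitted on
the nine training folds only; the fingerprint of the data each propensity
model was fitted on is kept so tests can prove the held-out fold never
leaked into its own encoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import metrics as _metrics
from .features import (
    FamilyDescriptor,
    FeatureMatrix,
    FeatureSpec,
    PhysChemTable,
    PropensityModel,
    build_feature_matrix,
    fit_propensities,
)
from .metrics import MetricsReport
from .sequence_core import LabeledDataset, RNAFragment

DEFAULT_SEED = 42


@dataclass(frozen=True)
class SVMGrid:
    """Geometric (C, kernel scale) search grid."""

    box_constraints: tuple[float, ...]
    kernel_scales: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, seq in (("box_constraints", self.box_constraints),
                          ("kernel_scales", self.kernel_scales)):
            if not seq:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"{name} must be strictly increasing")

    @classmethod
    def from_exponents(cls, c_lo: int = -5, c_hi: int = 15,
                       s_lo: int = -10, s_hi: int = 6,
                       step: int = 1) -> "SVMGrid":
        return cls(
            box_constraints=tuple(2.0**e for e in range(c_lo, c_hi + 1, step)),
            kernel_scales=tuple(2.0**e for e in range(s_lo, s_hi + 1, step)),
        )

    @classmethod
    def full(cls) -> "SVMGrid":
        """Full 21 x 17 grid: C in 2^-5..2^15, scale in 2^-10..2^6."""
        return cls.from_exponents(step=1)

    @classmethod
    def coarse(cls, step: int = 2) -> "SVMGrid":
        """Same bounds, wider exponent step; the default for fast runs."""
        return cls.from_exponents(step=step)

    @classmethod
    def single(cls, C: float, kernel_scale: float) -> "SVMGrid":
        return cls(box_constraints=(C,), kernel_scales=(kernel_scale,))

    def points(self) -> list[tuple[float, float]]:
        return [(c, s) for c in self.box_constraints for s in self.kernel_scales]

    def __len__(self) -> int:
        return len(self.box_constraints) * len(self.kernel_scales)


def _gamma(kernel_scale: float) -> float:
    return 1.0 / kernel_scale**2


@dataclass
class ColumnScaler:
    """Per-column z-scoring with zero-variance columns dropped."""

    mean: np.ndarray
    sd: np.ndarray
    retained: np.ndarray  # boolean mask over original columns

    @classmethod
    def fit(cls, X: np.ndarray) -> "ColumnScaler":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        retained = sd > 0
        return cls(mean=mean, sd=sd, retained=retained)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xr = X[:, self.retained]
        return (Xr - self.mean[self.retained]) / self.sd[self.retained]

    @property
    def n_dropped(self) -> int:
        return int((~self.retained).sum())


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus everything needed to encode new fragments.

    The decision function is stored explicitly (support vectors, dual
    coefficients, intercept) so scoring and serialization do not depend on
    pickling an estimator object.
    """

    box_constraint: float
    kernel_scale: float
    scaler: ColumnScaler
    feature_spec: FeatureSpec
    propensity: PropensityModel | None
    lambda_flank: int
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    decision_threshold: float = 0.0
    ksnpf_denominator: str = "window"
    training_fingerprint: str = ""

    def decision_function(self, X_scaled: np.ndarray) -> np.ndarray:
        K = rbf_kernel(X_scaled, self.support_vectors, gamma=_gamma(self.kernel_scale))
        return K @ self.dual_coef + self.intercept

    def score_features(self, X_raw: np.ndarray) -> np.ndarray:
        return self.decision_function(self.scaler.transform(X_raw))


@dataclass
class CVResult:
    """Cross-validation outcome at the selected hyper-parameters."""

    fold_reports: list[MetricsReport]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    box_constraint: float
    kernel_scale: float
    seed: int
    fold_fingerprints: list[str]  # fingerprint of each fold's training subset
    feature_spec: FeatureSpec | None = None

    @property
    def auroc(self) -> float:
        """AUROC of the pooled held-out decision values."""
        return _metrics.auroc(self.pooled_scores, self.pooled_labels)

    @property
    def auprc(self) -> float:
        return _metrics.auprc(self.pooled_scores, self.pooled_labels)

    def mean_report(self) -> MetricsReport:
        """Fold-averaged threshold metrics plus pooled AUROC/AUPRC."""
        def avg(attr):
            return float(np.mean([getattr(r, attr) for r in self.fold_reports]))
        return MetricsReport(
            Sn=avg("Sn"), Sp=avg("Sp"), Pre=avg("Pre"), Acc=avg("Acc"),
            Mcc=avg("Mcc"), F1=avg("F1"),
            AUROC=self.auroc, AUPRC=self.auprc,
        )


def _validate_features(X: np.ndarray, provenance=None) -> None:
    bad = ~np.isfinite(X)
    if bad.any():
        cols = sorted(set(np.where(bad)[1].tolist()))
        names = (
            [provenance[c] for c in cols[:10]] if provenance is not None else cols[:10]
        )
        raise ValueError(f"non-finite feature values in columns {names}")


def _as_array(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, FeatureMatrix):
        return X.data, X.column_provenance
    return np.asarray(X, dtype=float), None


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float, kernel_scale: float) -> SVC:
    clf = SVC(C=C, kernel="rbf", gamma=_gamma(kernel_scale))
    clf.fit(X, y)
    return clf


def _select_grid_point(
    results: dict[tuple[float, float], float]
) -> tuple[float, float]:
    """Maximize AUROC; break ties toward smaller C, then larger kernel
    scale (the smoother model).  Independent of enumeration order."""
    return min(results, key=lambda p: (-results[p], p[0], -p[1]))


def train_svm(
    X,
    y,
    grid: SVMGrid,
    folds: int = 10,
    seed: int = DEFAULT_SEED,
    feature_spec: FeatureSpec | None = None,
    propensity: PropensityModel | None = None,
    lambda_flank: int = 20,
    ksnpf_denominator: str = "window",
    training_fingerprint: str = "",
) -> TrainedModel:
    """Grid-search (C, kernel scale) by mean CV AUROC, then refit on all data.

    With a single-point grid the search is skipped and the model is fitted
    directly.
    """
    X_arr, provenance = _as_array(X)
    y = np.asarray(y, dtype=int)
    _validate_features(X_arr, provenance)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels are degenerate (single class)")
    if len(y) < folds:
        raise ValueError(f"need at least folds={folds} samples")

    scaler = ColumnScaler.fit(X_arr)
    Xs = scaler.transform(X_arr)

    if len(grid) == 1:
        best_c, best_s = grid.points()[0]
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(Xs, y))
        results: dict[tuple[float, float], float] = {}
        for C, s in grid.points():
            aucs = []
            for tr, te in splits:
                clf = _fit_svc(Xs[tr], y[tr], C, s)
                scores = clf.decision_function(Xs[te])
                if y[te].min() == y[te].max():
                    continue
                aucs.append(_metrics.auroc(scores, y[te]))
            results[(C, s)] = float(np.mean(aucs)) if aucs else 0.0
        best_c, best_s = _select_grid_point(results)

    clf = _fit_svc(Xs, y, best_c, best_s)
    return TrainedModel(
        box_constraint=best_c,
        kernel_scale=best_s,
        scaler=scaler,
        feature_spec=feature_spec,
        propensity=propensity,
        lambda_flank=lambda_flank,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        ksnpf_denominator=ksnpf_denominator,
        training_fingerprint=training_fingerprint,
    )


def train_on_dataset(
    data: LabeledDataset,
    spec: FeatureSpec,
    grid: SVMGrid,
    folds: int = 10,
    seed: int = DEFAULT_SEED,
    ksnpf_denominator: str = "window",
    table: PhysChemTable | None = None,
) -> TrainedModel:
    """Fit propensities (if needed), build features, and train an SVM."""
    propensity = None
    if spec.needs_propensity:
        propensity = fit_propensities(data, gaps=spec.propensity_gaps)
    fm = build_feature_matrix(data, spec, propensity, table, ksnpf_denominator)
    return train_svm(
        fm, data.labels, grid, folds=folds, seed=seed,
        feature_spec=spec, propensity=propensity,
        lambda_flank=data.lambda_flank,
        ksnpf_denominator=ksnpf_denominator,
        training_fingerprint=data.fingerprint(),
    )


def predict_scores(
    model: TrainedModel, fragments: Sequence[RNAFragment]
) -> list[tuple[float, int]]:
    """Score fragments with a trained model; label 1 iff score >= threshold.

    Features are built with the model's own feature spec, propensity
    matrices and scaler, so scoring is deterministic and batch-order
    invariant.
    """
    if not fragments:
        return []
    for f in fragments:
        if f.lambda_flank != model.lambda_flank:
            raise ValueError(
                f"fragment lambda_flank={f.lambda_flank} does not match "
                f"model lambda_flank={model.lambda_flank}"
            )
    if model.feature_spec is None:
        raise ValueError("model carries no feature spec")
    data = LabeledDataset(
        fragments=list(fragments),
        labels=np.zeros(len(fragments), dtype=int),
        lambda_flank=model.lambda_flank,
    )
    fm = build_feature_matrix(
        data, model.feature_spec, model.propensity,
        ksnpf_denominator=model.ksnpf_denominator,
    )
    scores = model.score_features(fm.data)
    return [(float(s), int(s >= model.decision_threshold)) for s in scores]


def cross_validate(
    data: LabeledDataset,
    spec: FeatureSpec,
    grid: SVMGrid,
    folds: int = 10,
    seed: int = DEFAULT_SEED,
    ksnpf_denominator: str = "window",
    table: PhysChemTable | None = None,
) -> CVResult:
    """Stratified k-fold CV with per-fold propensity and scaler refits.

    For every grid point the same folds are scored; the point with the
    highest mean held-out AUROC is selected and its per-fold metrics and
    pooled scores are reported.  Hyper-parameter selection and the reported
    metrics share folds, which is mildly optimistic but mirrors common
    practice for this class of predictor.
    """
    n_pos, n_neg = data.n_pos, data.n_neg
    if min(n_pos, n_neg) < folds:
        raise ValueError(
            f"need at least {folds} samples per class, got {n_pos}+/{n_neg}-"
        )
    table = table or PhysChemTable.default()
    y = data.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    static_spec = [d for d in spec if not d.needs_propensity]
    dynamic_spec = [d for d in spec if d.needs_propensity]
    static_X = None
    if static_spec:
        static_X = build_feature_matrix(
            data, FeatureSpec(tuple(static_spec)), None, table, ksnpf_denominator
        ).data

    # Per-fold feature matrices (propensities fitted on training folds only).
    fold_data = []
    fold_fingerprints = []
    for tr, te in splits:
        train_sub = data.subset(tr)
        blocks_tr, blocks_te = [], []
        if dynamic_spec:
            prop = fit_propensities(train_sub, gaps=spec.propensity_gaps)
            assert prop.fitted_on == train_sub.fingerprint()
            dyn = FeatureSpec(tuple(dynamic_spec))
            blocks_tr.append(build_feature_matrix(train_sub, dyn, prop, table).data)
            blocks_te.append(
                build_feature_matrix(data.subset(te), dyn, prop, table).data
            )
            fold_fingerprints.append(prop.fitted_on)
        else:
            fold_fingerprints.append(train_sub.fingerprint())
        if static_X is not None:
            blocks_tr.append(static_X[tr])
            blocks_te.append(static_X[te])
        X_tr = np.hstack(blocks_tr)
        X_te = np.hstack(blocks_te)
        scaler = ColumnScaler.fit(X_tr)
        fold_data.append((scaler.transform(X_tr), scaler.transform(X_te), y[tr], y[te]))

    # Grid search: mean held-out AUROC per point over the same folds.
    results: dict[tuple[float, float], float] = {}
    fold_scores_cache: dict[tuple[float, float], list[np.ndarray]] = {}
    for C, s in grid.points():
        aucs, per_fold_scores = [], []
        for X_tr, X_te, y_tr, y_te in fold_data:
            clf = _fit_svc(X_tr, y_tr, C, s)
            scores = clf.decision_function(X_te)
            per_fold_scores.append(scores)
            if y_te.min() != y_te.max():
                aucs.append(_metrics.auroc(scores, y_te))
        results[(C, s)] = float(np.mean(aucs)) if aucs else 0.0
        fold_scores_cache[(C, s)] = per_fold_scores

    best = _select_grid_point(results)
    best_scores = fold_scores_cache[best]
    fold_reports = [
        _metrics.score_report(sc, y_te)
        for sc, (_, _, _, y_te) in zip(best_scores, fold_data)
    ]
    pooled_scores = np.concatenate(best_scores)
    pooled_labels = np.concatenate([y_te for _, _, _, y_te in fold_data])
    return CVResult(
        fold_reports=fold_reports,
        pooled_scores=pooled_scores,
        pooled_labels=pooled_labels,
        box_constraint=best[0],
        kernel_scale=best[1],
        seed=seed,
        fold_fingerprints=fold_fingerprints,
        feature_spec=spec,
    )


# ---------------------------------------------------------------------------
# Model artifact serialization (single .npz: JSON manifest + numeric arrays)
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _spec_to_json(spec: FeatureSpec) -> list[dict]:
    return [
        {"family": d.family, "K": d.K, "lambda_pse": d.lambda_pse, "w": d.w}
        for d in spec
    ]


def _spec_from_json(obj: list[dict]) -> FeatureSpec:
    return FeatureSpec(
        tuple(
            FamilyDescriptor(
                family=d["family"], K=d["K"],
                lambda_pse=d["lambda_pse"], w=d["w"],
            )
            for d in obj
        )
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write the model as one .npz archive: a JSON manifest + arrays."""
    if model.feature_spec is None:
        raise ValueError("cannot serialize a model without a feature spec")
    manifest = {
        "format_version": _FORMAT_VERSION,
        "box_constraint": model.box_constraint,
        "kernel_scale": model.kernel_scale,
        "decision_threshold": model.decision_threshold,
        "lambda_flank": model.lambda_flank,
        "ksnpf_denominator": model.ksnpf_denominator,
        "training_fingerprint": model.training_fingerprint,
        "feature_spec": _spec_to_json(model.feature_spec),
        "has_propensity": model.propensity is not None,
        "propensity_gaps": sorted(model.propensity.kspsdp) if model.propensity else [],
        "propensity_fitted_on": model.propensity.fitted_on if model.propensity else "",
        "intercept": model.intercept,
    }
    arrays = {
        "manifest": np.array(json.dumps(manifest)),
        "support_vectors": model.support_vectors,
        "dual_coef": model.dual_coef,
        "scaler_mean": model.scaler.mean,
        "scaler_sd": model.scaler.sd,
        "scaler_retained": model.scaler.retained,
    }
    if model.propensity is not None:
        arrays["psnp"] = model.propensity.psnp
        for k, mat in model.propensity.kspsdp.items():
            arrays[f"kspsdp_{k}"] = mat
    np.savez_compressed(path, **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        manifest = json.loads(str(z["manifest"]))
        if manifest["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format {manifest['format_version']}")
        propensity = None
        if manifest["has_propensity"]:
            propensity = PropensityModel(
                psnp=z["psnp"],
                kspsdp={k: z[f"kspsdp_{k}"] for k in manifest["propensity_gaps"]},
                lambda_flank=manifest["lambda_flank"],
                fitted_on=manifest["propensity_fitted_on"],
            )
        return TrainedModel(
            box_constraint=manifest["box_constraint"],
            kernel_scale=manifest["kernel_scale"],
            scaler=ColumnScaler(
                mean=z["scaler_mean"], sd=z["scaler_sd"], retained=z["scaler_retained"]
            ),
            feature_spec=_spec_from_json(manifest["feature_spec"]),
            propensity=propensity,
            lambda_flank=manifest["lambda_flank"],
            support_vectors=z["support_vectors"],
            dual_coef=z["dual_coef"],
            intercept=manifest["intercept"],
            decision_threshold=manifest["decision_threshold"],
            ksnpf_denominator=manifest["ksnpf_denominator"],
            training_fingerprint=manifest["training_fingerprint"],
        )
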
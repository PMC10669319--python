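"""End-to-end orchestration.

Protocol: stratified train/test split -> hyperparameter search with the
pelican optimizer, scoring candidates by stratified k-fold cross-validated
classification error on the training split only -> retrain the full stack
(backbone -> feature standardisation -> PCA -> ANFIS) on the training split
with the best hyperparameters -> evaluate on both splits with the per-class
metric suite. The test split never influences feature reduction, tuning or
training.
"""

from __future__ import annotations

import hashlib
import json
import warnings as _warnings
from dataclasses import dataclass, field, asdict
from math import ceil, floor
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from . import anfis as _anfis
from . import epoa as _epoa
from .backbone import BackboneConfig, TrainHyperparams, build_backbone, extract_features, train_backbone
from .metrics import ConfusionMatrix, confusion, metrics_table
from .synthdata import MITOSIS, NON_MITOSIS, PatchDataset, SynthConfig, generate_dataset, load_dataset

__all__ = [
    "SplitSpec",
    "HyperparamSpec",
    "HyperparamSpace",
    "ExperimentConfig",
    "EvaluationReport",
    "stratified_split",
    "reduce_features",
    "error_rate",
    "error_rate_fitness",
    "tune_hyperparameters",
    "train_stack",
    "ClassifierStack",
    "run_experiment",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def stratified_split(labels, spec: SplitSpec):
    """Per-class allocation: the first-listed class takes the ceiling of
    fraction * class_size, the second the floor; order within a class is a
    seeded shuffle. Returns (train_ids, test_ids) as index arrays."""
    labels = list(labels)
    classes = list(dict.fromkeys(labels))  # first-appearance order
    if len(classes) < 2:
        raise ValueError("need both classes present to split")
    rng = np.random.default_rng(spec.seed)
    train, test = [], []
    for k, cls in enumerate(classes):
        idx = np.array([i for i, lab in enumerate(labels) if lab == cls])
        if spec.stratified:
            rng.shuffle(idx)
        n = spec.train_fraction * idx.size
        n_train = ceil(n) if k == 0 else floor(n)
        train.extend(idx[:n_train].tolist())
        test.extend(idx[n_train:].tolist())
    return np.array(sorted(train)), np.array(sorted(test))


# ---------------------------------------------------------------------------
# hyperparameter space


@dataclass(frozen=True)
class HyperparamSpec:
    """One tunable: box bounds on the encoded (real) axis plus a codec."""

    name: str
    low: float
    high: float
    codec: str = "float"  # float | log10 | int

    def decode(self, value: float):
        if self.codec == "log10":
            return float(10.0**value)
        if self.codec == "int":
            return int(round(value))
        return float(value)


_DEFAULT_SPECS = (
    HyperparamSpec("learning_rate", -4.0, -1.0, "log10"),
    HyperparamSpec("batch_size", 8, 32, "int"),
    HyperparamSpec("weight_decay", -6.0, -3.0, "log10"),
    HyperparamSpec("backbone_epochs", 3, 15, "int"),
    HyperparamSpec("anfis_n_mf", 2, 3, "int"),
    HyperparamSpec("anfis_epochs", 5, 50, "int"),
    HyperparamSpec("pca_components", 2, 6, "int"),
)


@dataclass(frozen=True)
class HyperparamSpace:
    """The tuned set: optimizer rates on a log10 axis, integer sizes decoded
    by rounding the continuous coordinate."""

    specs: tuple[HyperparamSpec, ...] = _DEFAULT_SPECS

    def to_search_space(self) -> _epoa.SearchSpace:
        return _epoa.SearchSpace(
            np.array([s.low for s in self.specs], dtype=float),
            np.array([s.high for s in self.specs], dtype=float),
        )

    def decode(self, vector) -> dict:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (len(self.specs),):
            raise ValueError(f"expected a {len(self.specs)}-vector")
        return {s.name: s.decode(v) for s, v in zip(self.specs, vector)}

    def midpoint(self) -> np.ndarray:
        return np.array([(s.low + s.high) / 2.0 for s in self.specs])


# ---------------------------------------------------------------------------
# feature reduction


def reduce_features(features: np.ndarray, n_components: int, fit_ids):
    """Standardise then project onto principal components, both fitted on
    the ``fit_ids`` rows only and applied to all rows."""
    features = np.asarray(features, dtype=float)
    fit_ids = np.asarray(fit_ids, dtype=int)
    scaler = StandardScaler().fit(features[fit_ids])
    pca = PCA(n_components=n_components, svd_solver="full").fit(
        scaler.transform(features[fit_ids])
    )
    reduced = pca.transform(scaler.transform(features))
    return reduced, (scaler, pca)


# ---------------------------------------------------------------------------
# classifier stack


def _encode_labels(labels) -> np.ndarray:
    return np.array([1 if lab == MITOSIS else 0 for lab in labels], dtype=int)


def _decode_labels(y: np.ndarray) -> list:
    return [MITOSIS if v == 1 else NON_MITOSIS for v in y]


@dataclass
class ClassifierStack:
    backbone: object
    scaler: StandardScaler
    pca: PCA
    anfis_model: _anfis.ANFISModel
    history: list

    def predict(self, images) -> list:
        feats = extract_features(self.backbone, images).values
        reduced = self.pca.transform(self.scaler.transform(feats))
        return _decode_labels(_anfis.predict(self.anfis_model, reduced))


def train_stack(
    images,
    labels,
    hp: dict,
    seed: int,
    backbone_config: BackboneConfig | None = None,
) -> ClassifierStack:
    """Train backbone, fit the reduction and the ANFIS head on one split."""
    cfg = backbone_config or BackboneConfig.desk()
    y = _encode_labels(labels)
    model = build_backbone(cfg, seed=seed)
    hyper = TrainHyperparams(
        learning_rate=hp["learning_rate"],
        batch_size=hp["batch_size"],
        weight_decay=hp["weight_decay"],
        epochs=hp["backbone_epochs"],
        seed=seed,
    )
    history = train_backbone(model, np.asarray(images), y, hyper)
    feats = extract_features(model, np.asarray(images)).values
    n_comp = min(hp["pca_components"], feats.shape[0] - 1, feats.shape[1])
    reduced, (scaler, pca) = reduce_features(feats, n_comp, np.arange(feats.shape[0]))
    am = _anfis.ANFISModel.from_grid(reduced, hp["anfis_n_mf"])
    _anfis.fit(
        am,
        reduced,
        y.astype(float),
        _anfis.ANFISTrainConfig(epochs=hp["anfis_epochs"], seed=seed),
    )
    return ClassifierStack(model, scaler, pca, am, history)


# ---------------------------------------------------------------------------
# fitness


def error_rate(y_true, y_pred) -> float:
    """Classification error, percent: 100 * misclassified / total."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    wrong = sum(1 for t, p in zip(y_true, y_pred) if t != p)
    return 100.0 * wrong / len(y_true)


def error_rate_fitness(
    hyperparam_vector,
    images,
    labels,
    space: HyperparamSpace | None = None,
    cv_folds: int = 3,
    seed: int = 0,
    backbone_config: BackboneConfig | None = None,
) -> float:
    """Mean stratified-CV classification error (percent) of the full stack
    under the decoded hyperparameters; a diverging fold scores 100."""
    space = space or HyperparamSpace()
    hp = space.decode(hyperparam_vector)
    images = np.asarray(images)
    y = _encode_labels(labels)
    labels = list(labels)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_errors = []
    for tr, va in skf.split(images, y):
        try:
            stack = train_stack(
                images[tr], [labels[i] for i in tr], hp, seed, backbone_config
            )
            pred = stack.predict(images[va])
            fold_errors.append(error_rate([labels[i] for i in va], pred))
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            _warnings.warn(f"fold scored 100 after training failure: {exc}", stacklevel=2)
            fold_errors.append(100.0)
    return float(np.mean(fold_errors))


def tune_hyperparameters(
    images,
    labels,
    space: HyperparamSpace | None = None,
    epoa_config: _epoa.EPOAConfig | None = None,
    cv_folds: int = 3,
    seed: int = 0,
    backbone_config: BackboneConfig | None = None,
):
    """Run the pelican optimizer over the encoded space; returns the decoded
    best hyperparameters and the raw optimization result."""
    space = space or HyperparamSpace()
    epoa_config = epoa_config or _epoa.EPOAConfig(pop_size=5, max_iter=5, seed=seed)
    cache: dict[tuple, float] = {}

    def objective(vec):
        # the fitness depends on the vector only through the decoded
        # hyperparameters and is deterministic, so repeats (integer rounding,
        # clamped bounds) are memoised
        key = tuple(sorted(space.decode(vec).items()))
        if key not in cache:
            cache[key] = error_rate_fitness(
                vec, images, labels, space, cv_folds, seed, backbone_config
            )
        return cache[key]

    result = _epoa.optimize(objective, space.to_search_space(), epoa_config)
    return space.decode(result.best_position), result


# ---------------------------------------------------------------------------
# experiment


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    data_dir: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    backbone: BackboneConfig = field(default_factory=BackboneConfig.desk)
    hyperparams: HyperparamSpace = field(default_factory=HyperparamSpace)
    epoa_pop_size: int = 5
    epoa_max_iter: int = 5
    cv_folds: int = 3

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        """Build from a plain (YAML/JSON) mapping with strict key checking."""
        doc = dict(doc or {})
        kwargs = {}
        nested = {
            "synth": SynthConfig,
            "split": SplitSpec,
            "backbone": BackboneConfig,
            "hyperparams": None,
        }
        for key, sub in list(doc.items()):
            if key in nested:
                if key == "hyperparams":
                    specs = tuple(HyperparamSpec(**s) for s in sub)
                    kwargs[key] = HyperparamSpace(specs)
                    continue
                known = nested[key].__dataclass_fields__
                extra = set(sub) - set(known)
                if extra:
                    raise ValueError(f"unknown keys in '{key}': {sorted(extra)}")
                for name in ("stage_units", "nuclei_per_patch", "radius_range",
                             "background_rgb", "nucleus_rgb",
                             "mitotic_axis_ratio", "nonmitotic_axis_ratio"):
                    if name in sub:
                        sub[name] = tuple(sub[name])
                kwargs[key] = nested[key](**sub)
            elif key in cls.__dataclass_fields__:
                kwargs[key] = doc[key]
            else:
                raise ValueError(f"unknown config key: {key!r}")
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class EvaluationReport:
    phases: dict
    best_hyperparams: dict
    trace: list
    seed: int
    config_hash: str

    def to_dict(self) -> dict:
        return asdict(self)


def run_experiment(config: ExperimentConfig, out_dir=None) -> EvaluationReport:
    """Full protocol; optionally writes report.json, metrics.csv,
    confusion.csv and trace.csv under ``out_dir``."""
    try:
        dataset = _load_or_generate(config)
        train_ids, test_ids = stratified_split(
            dataset.labels,
            SplitSpec(config.split.train_fraction, config.split.stratified, config.seed),
        )
        images = np.asarray(dataset.images)
        labels = list(dataset.labels)
        tr_imgs = images[train_ids]
        tr_labels = [labels[i] for i in train_ids]
    except Exception as exc:
        raise RuntimeError(f"[data] stage failed: {exc}") from exc

    try:
        epoa_config = _epoa.EPOAConfig(
            pop_size=config.epoa_pop_size, max_iter=config.epoa_max_iter, seed=config.seed
        )
        best_hp, result = tune_hyperparameters(
            tr_imgs,
            tr_labels,
            config.hyperparams,
            epoa_config,
            config.cv_folds,
            config.seed,
            config.backbone,
        )
    except Exception as exc:
        raise RuntimeError(f"[tune] stage failed: {exc}") from exc

    try:
        stack = train_stack(tr_imgs, tr_labels, best_hp, config.seed, config.backbone)
    except Exception as exc:
        raise RuntimeError(f"[train] stage failed: {exc}") from exc

    try:
        phases = {}
        for phase, ids in (("train", train_ids), ("test", test_ids)):
            pred = stack.predict(images[ids])
            cm = confusion([labels[i] for i in ids], pred)
            phases[phase] = {
                "confusion": cm.counts.tolist(),
                "classes": list(cm.classes),
                "metrics": metrics_table(cm),
            }
    except Exception as exc:
        raise RuntimeError(f"[evaluate] stage failed: {exc}") from exc

    report = EvaluationReport(
        phases=phases,
        best_hyperparams=best_hp,
        trace=[float(v) for v in result.trace],
        seed=config.seed,
        config_hash=config.config_hash(),
    )
    if out_dir is not None:
        _write_artifacts(report, result, out_dir)
    return report


def _load_or_generate(config: ExperimentConfig) -> PatchDataset:
    if config.data_dir:
        return load_dataset(config.data_dir)
    synth = config.synth
    if synth.seed != config.seed:
        from dataclasses import replace

        synth = replace(synth, seed=config.seed)
    return generate_dataset(synth)


def _write_artifacts(report: EvaluationReport, result, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))

    rows = []
    for phase, payload in report.phases.items():
        for cls, row in payload["metrics"].items():
            rows.append({"phase": phase, "class": cls, **row})
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)

    cm_rows = []
    for phase, payload in report.phases.items():
        for i, true_cls in enumerate(payload["classes"]):
            for j, pred_cls in enumerate(payload["classes"]):
                cm_rows.append(
                    {
                        "phase": phase,
                        "true": true_cls,
                        "predicted": pred_cls,
                        "count": payload["confusion"][i][j],
                    }
                )
    pd.DataFrame(cm_rows).to_csv(out_dir / "confusion.csv", index=False)
    _epoa.save_trace(result, out_dir / "trace.csv")
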
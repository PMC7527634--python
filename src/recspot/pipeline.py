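"""End-to-end pipeline: extract blocks, rank, combine, train, evaluate.

A :class:`PipelineSpec` bundles every stage's parameters: the four feature
extractors, per-block selection sizes, the hybrid mixing weights and the
classifier (network config or conventional baseline).  ``fit_pipeline``
fits the trainable stages (rankings, standardization, classifier) on a
training index set and returns a :class:`FittedPipeline` that can score any
other rows of the same extracted blocks — this is the unit the
cross-validator refits per fold.

``run_pipeline`` executes the whole study from a config: simulate or read
sequences, extract all blocks, rank, combine, cross-validate, and write
every intermediate plus a manifest into a run directory.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .errors import ParameterError
from .evaluation import (
    CvReport,
    LeakageMode,
    compute_metrics,
    confusion,
    roc_auc,
    stratified_folds,
)
from .features import (
    BankParams,
    FeatureMatrix,
    GdcParams,
    PsetncParams,
    RccParams,
    extract_block,
)
from .hybrid import BlockSizes, HybridSpec, build_hybrid
from .model import BaselineSpec, DnnConfig, forward, predict, train_dnn
from .selection import SelectionSpec, select_top, svm_rfe_rank
from .sequences import SequenceDataset, read_fasta, write_fasta
from .simulate import SimulationSpec, generate_synthetic_dataset

logger = logging.getLogger(__name__)

#: map block tag -> (extract_block method name, params attribute)
_TAG_METHOD = {"G": "gdc", "R": "rcc", "P": "psetnc", "H": "bank"}


@dataclass(frozen=True)
class PipelineSpec:
    """Every stage's parameters for one end-to-end run."""

    gdc: GdcParams = GdcParams()
    rcc: RccParams = RccParams()
    psetnc: PsetncParams = PsetncParams()
    bank: BankParams = BankParams()
    selection: SelectionSpec = SelectionSpec()
    hybrid: HybridSpec = HybridSpec()  # default: a=1, lam_mix=0 (group G3)
    classifier: Union[DnnConfig, BaselineSpec] = DnnConfig()
    standardize: bool = True

    def needed_tags(self) -> list[str]:
        """Block tags with a nonzero take under the hybrid weights."""
        return [t for t, n in self.hybrid.take_counts().items() if n > 0]

    def params_for(self, tag: str):
        return {"G": self.gdc, "R": self.rcc, "P": self.psetnc, "H": self.bank}[tag]


def extract_needed_blocks(
    dataset: SequenceDataset, spec: PipelineSpec
) -> dict[str, FeatureMatrix]:
    """Extract every block the hybrid spec draws from (rows in dataset order)."""
    return {
        tag: extract_block(dataset, _TAG_METHOD[tag], spec.params_for(tag))
        for tag in spec.needed_tags()
    }


def rank_blocks(
    blocks: dict[str, FeatureMatrix],
    labels,
    spec: PipelineSpec,
    train_idx: Optional[np.ndarray] = None,
) -> dict[str, FeatureMatrix]:
    """SVM-RFE-rank each block on the (training) rows and keep its selected top.

    Returns each block restricted to its selected features, columns in rank
    order, still covering *all* rows.  Ranking is skipped when a block keeps
    every feature it has (order is then immaterial downstream prefixes aside),
    except that a partial hybrid take still requires the ranking.
    """
    takes = spec.hybrid.take_counts()
    y = np.asarray(labels)
    out: dict[str, FeatureMatrix] = {}
    for tag, matrix in blocks.items():
        n_select = min(spec.selection.size_for(tag), len(matrix.feature_names))
        train = matrix if train_idx is None else matrix.subset_rows(list(train_idx))
        y_train = y if train_idx is None else y[train_idx]
        if n_select == len(matrix.feature_names) and takes[tag] >= n_select:
            # every feature survives selection and the hybrid takes them all:
            # the registry order is already a valid ranking
            out[tag] = matrix
            continue
        ranking = svm_rfe_rank(train, labels=list(y_train))
        out[tag] = matrix.select_columns(select_top(ranking, n_select))
    return out


@dataclass
class FittedPipeline:
    """Selected blocks, fitted scaler and trained classifier for one training set."""

    spec: PipelineSpec
    hybrid_matrix: FeatureMatrix  # all rows, selected+combined columns
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    classifier_model: object  # TrainedDnn or fitted sklearn estimator

    def _design(self, idx) -> np.ndarray:
        X = self.hybrid_matrix.values[list(idx)]
        return (X - self.scaler_mean) / self.scaler_std

    def predict(self, idx) -> np.ndarray:
        if isinstance(self.spec.classifier, DnnConfig):
            return predict(self.classifier_model, self._design(idx))
        return self.classifier_model.predict(self._design(idx))

    def predict_proba_hotspot(self, idx) -> np.ndarray:
        """P(hotspot) per sample (class 0)."""
        X = self._design(idx)
        if isinstance(self.spec.classifier, DnnConfig):
            return forward(self.classifier_model, X)[:, 0]
        model = self.classifier_model
        if hasattr(model, "predict_proba"):
            proba = model.predict_proba(X)
            return proba[:, list(model.classes_).index(0)]
        if hasattr(model, "decision_function"):
            # decision_function is signed toward class 1; flip for P(hotspot)
            d = model.decision_function(X)
            return 1.0 / (1.0 + np.exp(d))
        return (model.predict(X) == 0).astype(float)


def fit_pipeline(
    spec: PipelineSpec,
    blocks: dict[str, FeatureMatrix],
    labels,
    train_idx: Optional[np.ndarray] = None,
    rank_on_train_only: bool = True,
    seed: Optional[int] = None,
) -> FittedPipeline:
    """Fit rankings, hybrid combination, scaler and classifier.

    *blocks* are full extracted matrices over all rows; *train_idx* names the
    training rows (None = all).  When *rank_on_train_only* is False the
    rankings are assumed to have been applied already (whole-dataset mode) and
    *blocks* must hold rank-ordered selected columns.
    """
    y = np.asarray(labels, dtype=int)
    if train_idx is None:
        train_idx = np.arange(len(y))
    train_idx = np.asarray(train_idx)

    if rank_on_train_only:
        selected = rank_blocks(blocks, y, spec, train_idx)
    else:
        selected = blocks
    hybrid_all = build_hybrid(selected, spec.hybrid)

    X_train = hybrid_all.values[train_idx]
    if spec.standardize:
        mu, sd = X_train.mean(axis=0), X_train.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        mu = np.zeros(X_train.shape[1])
        sd = np.ones(X_train.shape[1])
    Xs = (X_train - mu) / sd

    if isinstance(spec.classifier, DnnConfig):
        cfg = replace(spec.classifier, input_width=Xs.shape[1])
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        model = train_dnn(Xs, y[train_idx], cfg)
    else:
        model = spec.classifier.build(seed if seed is not None else 0)
        model.fit(Xs, y[train_idx])
    return FittedPipeline(spec, hybrid_all, mu, sd, model)


def _cross_validate_impl(
    dataset: SequenceDataset,
    spec: PipelineSpec,
    k: int,
    seed: int,
    leakage_mode: LeakageMode,
) -> CvReport:
    """Backend for :func:`recspot.evaluation.cross_validate`."""
    if leakage_mode not in ("fold-internal-selection", "whole-dataset-selection"):
        raise ParameterError(f"unknown leakage_mode {leakage_mode!r}")
    y = np.asarray(dataset.numeric_labels(), dtype=int)
    blocks = extract_needed_blocks(dataset, spec)

    rank_per_fold = leakage_mode == "fold-internal-selection"
    if not rank_per_fold:
        blocks = rank_blocks(blocks, y, spec, train_idx=None)

    folds = stratified_folds(y, k=k, seed=seed)
    fold_assignment = np.full(len(y), -1, dtype=int)
    fold_metrics = []
    fold_confusions = []
    pooled_truth: list[int] = []
    pooled_pred: list[int] = []
    pooled_score: list[float] = []
    pooled_order: list[int] = []
    for fi, (train_idx, test_idx) in enumerate(folds):
        fold_assignment[test_idx] = fi
        fitted = fit_pipeline(
            spec, blocks, y, train_idx=train_idx, rank_on_train_only=rank_per_fold
        )
        pred = fitted.predict(test_idx)
        score = fitted.predict_proba_hotspot(test_idx)
        c = confusion(y[test_idx], pred)
        fold_confusions.append(c)
        fold_metrics.append(compute_metrics(c))
        pooled_truth.extend(y[test_idx])
        pooled_pred.extend(pred)
        pooled_score.extend(score)
        pooled_order.extend(test_idx)
        logger.info("fold %d/%d: acc=%.4f", fi + 1, k, fold_metrics[-1].acc)

    pooled_confusion = sum(fold_confusions[1:], fold_confusions[0])
    pooled = compute_metrics(pooled_confusion)
    roc = roc_auc(pooled_score, pooled_truth)
    return CvReport(
        fold_metrics=fold_metrics,
        pooled=pooled,
        pooled_confusion=pooled_confusion,
        fold_assignment=fold_assignment,
        leakage_mode=leakage_mode,
        roc=roc,
        k=k,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# run orchestration


_RUNCONFIG_KEYS = {
    "input_fasta",
    "label_source",
    "sidecar",
    "simulate",
    "group",
    "a",
    "lam_mix",
    "gaps",
    "rcc_ks",
    "lam",
    "w",
    "selection_sizes",
    "classifier",
    "dnn",
    "k_folds",
    "seed",
    "leakage_mode",
    "out_dir",
}


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run.

    Either ``input_fasta`` (with ``label_source``) or ``simulate`` (a
    :class:`SimulationSpec` field mapping) supplies the data.  ``group``
    selects one of the nine cataloged hybrid settings, or give ``a`` /
    ``lam_mix`` directly.
    """

    input_fasta: Optional[str] = None
    label_source: str = "header-token"
    sidecar: Optional[str] = None
    simulate: Optional[dict] = None
    group: Optional[str] = "G3"
    a: Optional[float] = None
    lam_mix: Optional[float] = None
    gaps: tuple[int, ...] = GdcParams().gaps
    rcc_ks: tuple[int, ...] = RccParams().ks
    lam: int = 2
    w: float = 0.1
    selection_sizes: dict = field(
        default_factory=lambda: {"g": 5, "r": 12, "p": 66, "h": 425}
    )
    classifier: str = "dnn"  # dnn | svm | knn | rf
    dnn: dict = field(default_factory=dict)  # DnnConfig overrides
    k_folds: int = 10
    seed: int = 0
    leakage_mode: str = "fold-internal-selection"
    out_dir: str = "recspot_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gaps", "rcc_ks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def pipeline_spec(self) -> PipelineSpec:
        sizes = self.selection_sizes
        sel = SelectionSpec(**sizes)
        block_sizes = BlockSizes(g=sel.g, r=sel.r, p=sel.p, h=sel.h)
        if self.a is not None or self.lam_mix is not None:
            hspec = HybridSpec(
                a=self.a if self.a is not None else 1.0,
                lam_mix=self.lam_mix if self.lam_mix is not None else 0.0,
                block_sizes=block_sizes,
            )
        else:
            hspec = HybridSpec.for_group(self.group or "G3", block_sizes)
        if self.classifier == "dnn":
            clf: Union[DnnConfig, BaselineSpec] = DnnConfig(
                **{"seed": self.seed + 6, **self.dnn}
            )
        else:
            clf = BaselineSpec(kind=self.classifier, params=dict(self.dnn))
        if "hidden_widths" in self.dnn and isinstance(clf, DnnConfig):
            clf = replace(clf, hidden_widths=tuple(self.dnn["hidden_widths"]))
        return PipelineSpec(
            gdc=GdcParams(gaps=self.gaps),
            rcc=RccParams(ks=self.rcc_ks),
            psetnc=PsetncParams(lam=self.lam, w=self.w),
            selection=sel,
            hybrid=hspec,
            classifier=clf,
        )

    def load_dataset(self) -> SequenceDataset:
        if self.input_fasta:
            return read_fasta(
                self.input_fasta, label_source=self.label_source, sidecar=self.sidecar
            )
        sim = dict(self.simulate or {})
        sim.setdefault("seed", self.seed)
        if "planted_kmers" in sim:
            sim["planted_kmers"] = tuple(sim["planted_kmers"])
        return generate_synthetic_dataset(SimulationSpec(**sim))


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write all intermediates plus a manifest.

    Returns the run directory containing: the dataset FASTA, one TSV per
    extracted block, the rank-ordered selected blocks, the hybrid matrix, the
    cross-validation report (JSON + per-fold TSV), pooled ROC points and a
    manifest recording versions, seed and parameters.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.pipeline_spec()

    dataset = config.load_dataset()
    write_fasta(dataset, out / "dataset.fasta")
    y = dataset.numeric_labels()

    blocks = extract_needed_blocks(dataset, spec)
    for tag, m in blocks.items():
        m.to_tsv(out / f"block_{tag}.tsv")
    selected = rank_blocks(blocks, y, spec, train_idx=None)
    for tag, m in selected.items():
        m.to_tsv(out / f"selected_{tag}.tsv")
    hybrid_matrix = build_hybrid(selected, spec.hybrid)
    hybrid_matrix.to_tsv(out / "hybrid.tsv")

    report = _cross_validate_impl(
        dataset, spec, config.k_folds, config.seed, config.leakage_mode  # type: ignore[arg-type]
    )
    (out / "cv_report.json").write_text(json.dumps(report.as_dict(), indent=2))
    _write_fold_tsv(report, out / "cv_folds.tsv")
    if report.roc:
        _write_roc_tsv(report.roc, out / "roc_points.tsv")

    manifest = {
        "recspot_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "hybrid_dimension": hybrid_matrix.shape[1],
        "n_records": len(dataset),
        "pooled_metrics": report.pooled.as_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("run complete: pooled acc=%.4f -> %s", report.pooled.acc, out)
    return out


def _write_fold_tsv(report: CvReport, path: Path) -> None:
    lines = ["fold\tacc\tsn\tsp\tmcc"]
    for i, m in enumerate(report.fold_metrics):
        lines.append(f"{i}\t{m.acc:.6f}\t{m.sn:.6f}\t{m.sp:.6f}\t{m.mcc:.6f}")
    m = report.pooled
    lines.append(f"pooled\t{m.acc:.6f}\t{m.sn:.6f}\t{m.sp:.6f}\t{m.mcc:.6f}")
    path.write_text("\n".join(lines) + "\n")


def _write_roc_tsv(roc, path: Path) -> None:
    lines = ["fpr\ttpr"] + [f"{x:.6f}\t{y:.6f}" for x, y in roc.points]
    path.write_text("\n".join(lines) + "\n")
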
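"""Contingency metrics, subject-level k-fold cross-validation, reporting
and t-SNE feature visualization.

Metrics follow the usual contingency definitions (accuracy, precision,
recall/sensitivity, F1, specificity). A metric whose denominator is zero
is *flagged undefined* and excluded from fold averaging rather than being
coerced to 0, which would silently bias small-fold reports. Splitting is
at the subject level — all of a subject's windows stay on one side of
every split — and stratified by class by default. Report confidence
half-widths are 95% Student-t intervals over the fold values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .core import SubjectRecord, Volume4D
from .pipeline import PipelineConfig, classify_subject, train_pipeline

__all__ = [
    "Metrics",
    "FoldAssignment",
    "EvaluationReport",
    "contingency_metrics",
    "kfold_split",
    "cross_validate",
    "tsne_embed",
    "write_report",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "specificity")


@dataclass(frozen=True)
class Metrics:
    """Contingency counts and the five derived rates.

    Undefined rates (zero denominator) carry NaN and appear in
    ``undefined``.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("tp", "tn", "fp", "fn", *METRIC_NAMES)}
        d["undefined"] = sorted(self.undefined)
        return d


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return float("nan"), True
    return num / den, False


def contingency_metrics(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    """Derive accuracy, precision, recall, F1 and specificity from counts."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    tp, tn, fp, fn = int(tp), int(tn), int(fp), int(fn)
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty contingency table")
    undefined: set[str] = set()
    accuracy = (tp + tn) / total
    precision, u = _ratio(tp, tp + fp)
    if u:
        undefined.add("precision")
    recall, u = _ratio(tp, tp + fn)
    if u:
        undefined.add("recall")
    specificity, u = _ratio(tn, tn + fp)
    if u:
        undefined.add("specificity")
    if "precision" in undefined or "recall" in undefined or precision + recall == 0:
        f1 = float("nan")
        undefined.add("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, precision=precision, recall=recall,
        f1=f1, specificity=specificity, undefined=frozenset(undefined),
    )


@dataclass(frozen=True)
class FoldAssignment:
    """Subject-level fold indices 0..K-1, aligned with the input records."""

    fold_of: tuple[int, ...]
    K: int
    stratified: bool
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_of) == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_of) != fold)


def kfold_split(
    records: Sequence[SubjectRecord],
    K: int,
    stratified: bool = True,
    seed: int = 0,
) -> FoldAssignment:
    """Disjoint, covering, size-balanced subject-level folds (seeded)."""
    n = len(records)
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of subjects ({n})")
    from sklearn.model_selection import KFold, StratifiedKFold

    fold_of = np.empty(n, dtype=int)
    if stratified:
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        labels = np.array([r.label for r in records])
        splits = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    for fold, (_, test_idx) in enumerate(splits):
        fold_of[test_idx] = fold
    return FoldAssignment(
        fold_of=tuple(int(f) for f in fold_of), K=K, stratified=stratified, seed=seed
    )


@dataclass
class EvaluationReport:
    """Per-fold metrics, their mean +/- 95% CI, and per-site breakdown."""

    per_fold: list[Metrics]
    mean: dict[str, float]
    ci_halfwidth: dict[str, float]
    per_site: dict[str, Metrics]
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "per_fold": [m.as_dict() for m in self.per_fold],
            "mean": self.mean,
            "ci_halfwidth": self.ci_halfwidth,
            "per_site": {s: m.as_dict() for s, m in sorted(self.per_site.items())},
            "metadata": self.metadata,
        }


def _summarize_folds(per_fold: Sequence[Metrics]) -> tuple[dict, dict]:
    from scipy import stats

    mean: dict[str, float] = {}
    ci: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = [getattr(m, name) for m in per_fold if name not in m.undefined]
        if not vals:
            mean[name] = float("nan")
            ci[name] = float("nan")
            continue
        mean[name] = float(np.mean(vals))
        if len(vals) < 2:
            ci[name] = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
            ci[name] = float(stats.t.ppf(0.975, len(vals) - 1) * sd / np.sqrt(len(vals)))
    return mean, ci


def _config_hash(config, seed: int) -> str:
    payload = json.dumps(
        {"config": asdict(config) if is_dataclass(config) else str(config),
         "seed": int(seed)},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cross_validate(
    records: Sequence[SubjectRecord],
    config: PipelineConfig,
    K: int,
    seed: int,
    volumes: Optional[Mapping[str, Volume4D]] = None,
    stratified: bool = True,
    pipeline_factory: Optional[Callable] = None,
) -> EvaluationReport:
    """Subject-level K-fold cross-validation of the full pipeline.

    For each fold the pipeline is trained from scratch on the training
    subjects and every held-out subject is classified; contingency counts
    are accumulated at the subject level. ``pipeline_factory(train_records,
    volumes, seed)`` may replace the default trainer; it must return an
    object accepting ``predict(record, volume) -> {0, 1}`` — used for
    oracle stubs in testing and for model variants.
    """
    folds = kfold_split(records, K, stratified=stratified, seed=seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s % 2**31) for s in ss.generate_state(K)]

    per_fold: list[Metrics] = []
    site_counts: dict[str, np.ndarray] = {}
    predictions: dict[str, int] = {}
    for fold in range(K):
        train_recs = [records[i] for i in folds.train_indices(fold)]
        test_recs = [records[i] for i in folds.test_indices(fold)]
        train_labels = {r.label for r in train_recs}
        if len(train_labels) < 2:
            raise ValueError(
                f"fold {fold} training split lost a class; use stratified=True"
            )
        if pipeline_factory is not None:
            predictor = pipeline_factory(train_recs, volumes, fold_seeds[fold])
            predict = predictor.predict
        else:
            model = train_pipeline(train_recs, config, fold_seeds[fold], volumes=volumes)

            def predict(rec, vol, _model=model):
                if vol is None:
                    from .core import load_volume

                    vol = load_volume(rec.volume_path)
                return classify_subject(_model, vol).y_final

        counts = np.zeros(4, dtype=int)  # tp, tn, fp, fn
        for rec in test_recs:
            vol = volumes.get(rec.subject_id) if volumes is not None else None
            y_hat = int(predict(rec, vol))
            predictions[rec.subject_id] = y_hat
            idx = _count_index(rec.label, y_hat)
            counts[idx] += 1
            site_counts.setdefault(rec.site, np.zeros(4, dtype=int))[idx] += 1
        per_fold.append(contingency_metrics(*counts))

    mean, ci = _summarize_folds(per_fold)
    per_site = {s: contingency_metrics(*c) for s, c in site_counts.items()}
    report = EvaluationReport(
        per_fold=per_fold,
        mean=mean,
        ci_halfwidth=ci,
        per_site=per_site,
        metadata={
            "K": K,
            "seed": int(seed),
            "stratified": stratified,
            "n_subjects": len(records),
            "fold_of": list(folds.fold_of),
            "subject_ids": [r.subject_id for r in records],
            "predictions": {sid: predictions[sid] for sid in sorted(predictions)},
            "config_hash": _config_hash(config, seed),
        },
    )
    return report


def _count_index(y_true: int, y_pred: int) -> int:
    if y_true == 1 and y_pred == 1:
        return 0  # tp
    if y_true == 0 and y_pred == 0:
        return 1  # tn
    if y_true == 0 and y_pred == 1:
        return 2  # fp
    return 3  # fn


def write_report(report: EvaluationReport, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report.as_dict(), indent=2, sort_keys=True))
    return path


def tsne_embed(
    features: np.ndarray,
    labels: Sequence[int],
    seed: int,
    out_path: Optional[Path | str] = None,
    perplexity: Optional[float] = None,
) -> np.ndarray:
    """Seeded 2-D t-SNE embedding of feature vectors, optionally plotted.

    Perplexity defaults to ``min(30, (n - 1) / 3)`` so small inputs remain
    valid. When ``out_path`` is given, a class-colored scatter is written
    there (PNG).
    """
    from sklearn.manifold import TSNE

    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    n, d = features.shape if features.ndim == 2 else (0, 0)
    if features.ndim != 2 or d < 2:
        raise ValueError("features must be (n, d) with d >= 2")
    if n < 5:
        raise ValueError("need at least 5 samples for a meaningful embedding")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    emb = TSNE(
        n_components=2, random_state=seed, init="pca", perplexity=perplexity
    ).fit_transform(features)
    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for lab, color, name in ((0, "tab:blue", "control"), (1, "tab:red", "ASD")):
            sel = labels == lab
            ax.scatter(emb[sel, 0], emb[sel, 1], s=12, c=color, label=name, alpha=0.8)
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        ax.legend(frameon=False)
        fig.tight_layout()
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return emb
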
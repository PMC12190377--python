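"""Per-window fusion, GBDT window classification, majority voting and the
two-stage training regime.

For window j (0-based, start index j*s) the temporal feature F_tem,j is
concatenated with the spatial feature of the window's *first* time point,
F_sp at index j*s, giving the fused vector of width d1 + d2. A
gradient-boosted tree ensemble classifies each fused window vector
(binary cross-entropy objective); the subject decision is the unweighted
majority over the k window labels, with k kept odd so ties cannot occur.

Training proceeds in two stages because boosted trees admit no gradient
path back into the encoders:

1. the spatial and temporal encoders are trained *jointly* with a
   temporary linear head on window-level binary cross-entropy, each
   window inheriting its subject's label (Adam, configurable learning
   rate / batch size / epochs);
2. the encoders are frozen, fused features are extracted for all training
   windows, and the GBDT is fitted on them.

All windows of a subject stay on one side of any train/test split;
splitting is the caller's job (see :mod:`brainwin.evaluate`).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from ._nn import Adam, Linear, bce_with_logits
from .core import SubjectRecord, Volume4D, load_volume
from .spatial import (
    SpatialEncoder,
    SpatialEncoderConfig,
    SpatialFeatureSeq,
    build_spatial_encoder,
    extract_spatial_features,
)
from .temporal import (
    TemporalEncoder,
    TemporalEncoderConfig,
    TemporalFeatureSet,
    WindowConfig,
    WindowSet,
    build_temporal_encoder,
    extract_temporal_features,
    segment_windows,
)

__all__ = [
    "GBDTConfig",
    "TrainConfig",
    "PipelineConfig",
    "FusedFeatureSet",
    "WindowPredictions",
    "PipelineModel",
    "fuse_features",
    "majority_vote",
    "train_window_classifier",
    "classify_subject",
    "train_pipeline",
    "save_pipeline",
    "load_pipeline",
    "toy_pipeline_config",
]


@dataclass(frozen=True)
class GBDTConfig:
    """Boosted-tree hyperparameters (unstated upstream; these are this
    package's defaults)."""

    n_trees: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Stage-1 encoder training regime.

    ``stage1_window_stride`` subsamples the windows used for encoder
    training (every n-th window start); the GBDT stage always sees every
    window. ``use_temporal=False`` gives the spatial-only ablation
    (3D-CNN + GBDT). ``weighted_vote`` switches the subject decision to
    mean-probability > 0.5 instead of the unweighted majority.
    """

    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    stage1_window_stride: int = 1
    use_temporal: bool = True
    weighted_vote: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")
        if self.stage1_window_stride < 1:
            raise ValueError("stage1_window_stride must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    spatial: SpatialEncoderConfig = field(default_factory=SpatialEncoderConfig)
    temporal: TemporalEncoderConfig = field(default_factory=TemporalEncoderConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    gbdt: GBDTConfig = field(default_factory=GBDTConfig)
    train: TrainConfig = field(default_factory=TrainConfig)


def toy_pipeline_config(
    t: int = 50,
    epochs: int = 6,
    stage1_window_stride: int = 2,
    use_temporal: bool = True,
) -> PipelineConfig:
    """Desk-scale configuration: small encoders, short stage-1 schedule.

    Sized so a full 5-fold cross-validation of a 40-subject (16, 16, 12, 50)
    cohort runs in a few minutes on one CPU.
    """
    return PipelineConfig(
        spatial=SpatialEncoderConfig.toy(),
        temporal=TemporalEncoderConfig.toy(),
        window=WindowConfig(t=t),
        gbdt=GBDTConfig(),
        train=TrainConfig(
            epochs=epochs,
            stage1_window_stride=stage1_window_stride,
            use_temporal=use_temporal,
        ),
    )


@dataclass
class FusedFeatureSet:
    """Fused per-window features with provenance.

    Row j concatenates F_tem,j with F_sp at time index ``spatial_index[j]``
    (the window's first frame); width is d1 + d2.
    """

    features: np.ndarray
    window_index: np.ndarray
    spatial_index: np.ndarray

    @property
    def k(self) -> int:
        return self.features.shape[0]


def fuse_features(
    tem: TemporalFeatureSet, sp: SpatialFeatureSeq, windows: WindowSet
) -> FusedFeatureSet:
    """Concatenate each window's temporal feature with the spatial feature
    of the window's first time point."""
    if tem.k != windows.k or tuple(tem.starts) != tuple(windows.starts):
        raise ValueError("temporal features are not aligned with the window set")
    starts = np.asarray(windows.starts, dtype=int)
    if starts.size and starts.max() >= sp.t:
        raise ValueError(
            f"spatial feature index {starts.max()} out of range for t={sp.t}"
        )
    fused = np.concatenate([tem.features, sp.features[starts]], axis=1)
    return FusedFeatureSet(
        features=fused,
        window_index=np.arange(windows.k),
        spatial_index=starts,
    )


def majority_vote(labels: Sequence[int]) -> int:
    """Unweighted majority over an odd number of binary window labels.

    Returns 1 iff the count of ones strictly exceeds k/2. Even k is a hard
    error: upstream window segmentation guarantees odd k, so an even vote
    indicates a pipeline bug, not a tie to be broken.
    """
    arr = np.asarray(labels)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("labels must be a non-empty 1-D sequence")
    if arr.size % 2 == 0:
        raise ValueError(f"vote requires an odd number of labels, got {arr.size}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary")
    return int(arr.sum() > arr.size / 2)


@dataclass
class WindowPredictions:
    """Per-window labels/probabilities and the voted subject label."""

    labels: np.ndarray
    probabilities: np.ndarray
    y_final: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.labels.shape != self.probabilities.shape:
            raise ValueError("labels and probabilities must be aligned")


def _make_gbdt(cfg: GBDTConfig):
    from lightgbm import LGBMClassifier

    return LGBMClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        learning_rate=cfg.learning_rate,
        objective="binary",
        random_state=cfg.seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )


def train_window_classifier(features: np.ndarray, labels: np.ndarray, cfg: GBDTConfig):
    """Fit the boosted-tree window classifier on pooled fused features."""
    features = np.asarray(features)
    labels = np.asarray(labels).ravel()
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features must be (n, d) aligned with labels")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain missing or non-finite values")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    model = _make_gbdt(cfg)
    model.fit(features, labels)
    return model


@dataclass
class PipelineModel:
    """The trained pipeline: both encoders, the GBDT, and metadata."""

    spatial_encoder: SpatialEncoder
    temporal_encoder: Optional[TemporalEncoder]
    gbdt: object
    config: PipelineConfig
    windows: WindowSet
    n_voxels: int
    in_shape: tuple[int, int, int]
    metadata: dict = field(default_factory=dict)

    @property
    def feature_dim(self) -> int:
        d = self.spatial_encoder.d1
        if self.temporal_encoder is not None:
            d += self.temporal_encoder.d2
        return d


def _subject_fused_features(model: PipelineModel, vol: Volume4D) -> np.ndarray:
    sp = extract_spatial_features(model.spatial_encoder, vol)
    if model.temporal_encoder is not None:
        tem = extract_temporal_features(model.temporal_encoder, vol, model.windows)
        return fuse_features(tem, sp, model.windows).features
    starts = np.asarray(model.windows.starts, dtype=int)
    return sp.features[starts]


def classify_subject(model: PipelineModel, vol: Volume4D) -> WindowPredictions:
    """Window-level classification and the voted subject decision.

    Label 1 denotes the clinical (ASD) class, 0 the control class. Window
    label is 1 exactly when its predicted probability exceeds 0.5.
    """
    if vol.spatial_shape != model.in_shape:
        raise ValueError(
            f"volume shape {vol.spatial_shape} does not match model shape {model.in_shape}"
        )
    if vol.t < model.windows.starts[-1] + model.windows.w:
        raise ValueError(
            f"volume has t={vol.t}, model windows need "
            f">= {model.windows.starts[-1] + model.windows.w}"
        )
    fused = _subject_fused_features(model, vol)
    probs = model.gbdt.predict_proba(fused)[:, 1]
    labels = (probs > 0.5).astype(int)
    if model.config.train.weighted_vote:
        y_final = int(probs.mean() > 0.5)
    else:
        y_final = majority_vote(labels)
    return WindowPredictions(labels=labels, probabilities=probs, y_final=y_final)


def _resolve_volumes(
    records: Sequence[SubjectRecord],
    volumes: Optional[Mapping[str, Volume4D]],
) -> dict[str, Volume4D]:
    out: dict[str, Volume4D] = {}
    for rec in records:
        if volumes is not None and rec.subject_id in volumes:
            out[rec.subject_id] = volumes[rec.subject_id]
        elif rec.volume_path is not None:
            out[rec.subject_id] = load_volume(rec.volume_path)
        else:
            raise ValueError(f"no volume available for subject {rec.subject_id}")
    return out


def train_pipeline(
    records: Sequence[SubjectRecord],
    config: PipelineConfig,
    seed: int,
    volumes: Optional[Mapping[str, Volume4D]] = None,
) -> PipelineModel:
    """Train the full pipeline on preprocessed, QC-passed subjects.

    ``volumes`` maps subject id to an in-memory :class:`Volume4D`; subjects
    missing from it are loaded from their ``volume_path``. Deterministic
    given ``seed``.
    """
    if len(records) < 2:
        raise ValueError("need at least two subjects")
    labels = np.array([r.label for r in records])
    if len(np.unique(labels)) < 2:
        raise ValueError("training cohort contains a single class")
    vols = _resolve_volumes(records, volumes)

    in_shape = next(iter(vols.values())).spatial_shape
    t = next(iter(vols.values())).t
    n_voxels = next(iter(vols.values())).voxel_matrix().shape[1]
    for rec in records:
        v = vols[rec.subject_id]
        if v.spatial_shape != in_shape or v.t != t:
            raise ValueError(
                f"subject {rec.subject_id} has shape {v.spatial_shape} x {v.t}, "
                f"expected {in_shape} x {t}"
            )

    wcfg = config.window
    if wcfg.t != t:
        wcfg = WindowConfig(t=t, w=wcfg.w, s=wcfg.s, enforce_odd_k=wcfg.enforce_odd_k)
    windows = segment_windows(wcfg)

    ss = np.random.SeedSequence(seed)
    seeds = [int(s % 2**31) for s in ss.generate_state(4)]
    spatial = build_spatial_encoder(config.spatial, in_shape, seeds[0])
    temporal = (
        build_temporal_encoder(config.temporal, n_voxels, seeds[1])
        if config.train.use_temporal
        else None
    )

    # per-subject arrays the two stages read from
    frames4d = {
        r.subject_id: np.moveaxis(vols[r.subject_id].data, -1, 0).astype(np.float32)
        for r in records
    }
    voxmats = (
        {r.subject_id: vols[r.subject_id].voxel_matrix() for r in records}
        if temporal is not None
        else {}
    )

    _train_encoders_stage1(records, frames4d, voxmats, spatial, temporal,
                           windows, config.train, seeds[2])

    model = PipelineModel(
        spatial_encoder=spatial,
        temporal_encoder=temporal,
        gbdt=None,
        config=PipelineConfig(
            spatial=config.spatial, temporal=config.temporal, window=wcfg,
            gbdt=config.gbdt, train=config.train,
        ),
        windows=windows,
        n_voxels=n_voxels,
        in_shape=in_shape,
        metadata={
            "seed": int(seed),
            "stage_seeds": seeds,
            "n_train_subjects": len(records),
            "k": windows.k,
            "d1": spatial.d1,
            "d2": temporal.d2 if temporal is not None else 0,
        },
    )

    # stage 2: frozen encoders -> fused features for every window -> GBDT
    feat_rows, win_labels = [], []
    for rec in records:
        fused = _subject_fused_features(model, vols[rec.subject_id])
        feat_rows.append(fused)
        win_labels.append(np.full(fused.shape[0], rec.label))
    gbdt_cfg = GBDTConfig(
        n_trees=config.gbdt.n_trees,
        max_depth=config.gbdt.max_depth,
        learning_rate=config.gbdt.learning_rate,
        seed=seeds[3],
    )
    model.gbdt = train_window_classifier(
        np.concatenate(feat_rows), np.concatenate(win_labels), gbdt_cfg
    )
    return model


def _train_encoders_stage1(
    records: Sequence[SubjectRecord],
    frames4d: Mapping[str, np.ndarray],
    voxmats: Mapping[str, np.ndarray],
    spatial: SpatialEncoder,
    temporal: Optional[TemporalEncoder],
    windows: WindowSet,
    tcfg: TrainConfig,
    seed: int,
) -> None:
    """Stage 1: joint encoder training with a temporary linear head on
    window-level binary cross-entropy (windows inherit subject labels)."""
    rng = np.random.default_rng(seed)
    d_total = spatial.d1 + (temporal.d2 if temporal is not None else 0)
    head = Linear(d_total, 1, rng, scale=float(1.0 / np.sqrt(d_total)))
    params = spatial.params() + (temporal.params() if temporal is not None else [])
    params += head.params()
    opt = Adam(params, lr=tcfg.learning_rate)

    starts_used = windows.starts[::tcfg.stage1_window_stride]
    samples = [
        (rec.subject_id, st, rec.label) for rec in records for st in starts_used
    ]
    if not samples or tcfg.epochs == 0:
        return
    order = np.arange(len(samples))
    w = windows.w
    for _ in range(tcfg.epochs):
        rng.shuffle(order)
        for lo in range(0, len(order), tcfg.batch_size):
            batch = [samples[i] for i in order[lo:lo + tcfg.batch_size]]
            frames = np.stack([frames4d[sid][st] for sid, st, _ in batch])
            y = np.array([lab for _, _, lab in batch], dtype=np.float32)
            opt.zero_grad()
            fsp = spatial.forward(frames, train=True)
            if temporal is not None:
                xw = np.stack([voxmats[sid][st:st + w] for sid, st, _ in batch])
                ftem = temporal.forward(xw, train=True)
                fused = np.concatenate([fsp, ftem], axis=1)
            else:
                fused = fsp
            logits = head.forward(fused, train=True)[:, 0]
            _, dlogits = bce_with_logits(logits, y)
            dfused = head.backward(dlogits[:, None])
            spatial.backward(dfused[:, : spatial.d1])
            if temporal is not None:
                temporal.backward(dfused[:, spatial.d1:])
            opt.step()


# ---------------------------------------------------------------------------
# serialization

def save_pipeline(model: PipelineModel, out_dir: Path | str) -> Path:
    """Serialize a trained pipeline to a directory.

    Layout: ``spatial.npz`` / ``temporal.npz`` (encoder weights),
    ``gbdt.txt`` (tree-ensemble model text), ``meta.json`` (configs, seeds,
    dimensions, window set).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "spatial.npz", **model.spatial_encoder.state_dict())
    if model.temporal_encoder is not None:
        np.savez(out_dir / "temporal.npz", **model.temporal_encoder.state_dict())
    model.gbdt.booster_.save_model(str(out_dir / "gbdt.txt"))
    meta = {
        "config": asdict(model.config),
        "in_shape": list(model.in_shape),
        "n_voxels": model.n_voxels,
        "window_starts": list(model.windows.starts),
        "window_w": model.windows.w,
        "metadata": model.metadata,
        "spatial_seed": model.spatial_encoder.seed,
        "temporal_seed": (
            model.temporal_encoder.seed if model.temporal_encoder is not None else None
        ),
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out_dir


def load_pipeline(model_dir: Path | str) -> PipelineModel:
    import lightgbm

    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "meta.json").read_text())
    c = meta["config"]
    config = PipelineConfig(
        spatial=SpatialEncoderConfig(**{**c["spatial"],
                                        "kernel_sizes": tuple(c["spatial"]["kernel_sizes"])}),
        temporal=TemporalEncoderConfig(**c["temporal"]),
        window=WindowConfig(**c["window"]),
        gbdt=GBDTConfig(**c["gbdt"]),
        train=TrainConfig(**c["train"]),
    )
    in_shape = tuple(meta["in_shape"])
    spatial = build_spatial_encoder(config.spatial, in_shape, meta["spatial_seed"])
    with np.load(model_dir / "spatial.npz") as st:
        spatial.load_state_dict(dict(st))
    temporal = None
    if (model_dir / "temporal.npz").exists():
        temporal = build_temporal_encoder(
            config.temporal, meta["n_voxels"], meta["temporal_seed"]
        )
        with np.load(model_dir / "temporal.npz") as st:
            temporal.load_state_dict(dict(st))
    booster = lightgbm.Booster(model_file=str(model_dir / "gbdt.txt"))
    gbdt = _BoosterAdapter(booster)
    return PipelineModel(
        spatial_encoder=spatial,
        temporal_encoder=temporal,
        gbdt=gbdt,
        config=config,
        windows=WindowSet(starts=tuple(meta["window_starts"]), w=meta["window_w"]),
        n_voxels=meta["n_voxels"],
        in_shape=in_shape,
        metadata=meta["metadata"],
    )


class _BoosterAdapter:
    """predict_proba facade over a raw lightgbm Booster."""

    def __init__(self, booster):
        self.booster_ = booster

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p1 = np.asarray(self.booster_.predict(x))
        return np.column_stack([1.0 - p1, p1])
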
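"""Two-stage classifier orchestration.

Stage 1 (grouped slice CNN) turns preprocessed slice groups into a feature
matrix; stage 2 is an extreme broad learning system (EBLS): an ordered list of
BLS blocks whose concatenated node outputs form the state matrix, with output
weights solved in closed form. The model grows in two directions without
retraining from scratch — new blocks append node columns, new imaging studies
append sample rows — via the incremental pseudoinverse updates of
:mod:`bladnet.bls_core`, which match batch refits.

``run_pipeline`` wires the whole protocol: seeded shuffle, 80/20 split,
stage-1 training on the training split only, feature extraction, EBLS fit,
and one-vs-rest evaluation on the held-out split.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import bls_core, evaluation, slice_cnn
from .bls_core import BLSBlock, BLSState
from .preprocess import PreprocessConfig, load_volume, preprocess_volume
from .slice_cnn import ExtractorConfig, FeatureMatrix, TrainedExtractor

logger = logging.getLogger(__name__)

__all__ = [
    "BLSConfig",
    "PipelineConfig",
    "EBLSModel",
    "PredictionResult",
    "fit_ebls",
    "add_block",
    "add_samples",
    "predict",
    "run_pipeline",
    "save_model",
    "load_model",
]


class ValidationError(ValueError):
    pass


# When lam is at or below this, predictions use the incrementally maintained
# pseudoinverse-path weights; above it, an exact ridge head is recomputed in
# closed form after every structural change.
RIDGE_EXACT_TOL = 1e-8


@dataclass
class BLSConfig:
    n_feature_nodes: int = 60
    n_enhance_nodes: int = 60
    initial_blocks: int = 2
    lam: float = 2.0**-30
    shrink: float = 0.8
    sae_iters: int = 0
    sae_lam: float = 1e-3
    seed: int = 7


@dataclass
class PipelineConfig:
    """Whole-pipeline settings.

    Defaults are sized for a single CPU: volumes are resampled in-plane to
    48 x 48 (the full 96-slice z extent is kept so trimming and grouping
    behave exactly as on the protocol grid) and the CNN trains for 6 epochs.
    """

    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(shape=(48, 48, 96))
    )
    extractor: ExtractorConfig = field(
        default_factory=lambda: ExtractorConfig(epochs=6)
    )
    bls: BLSConfig = field(default_factory=BLSConfig)
    split_frac: float = 0.8
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_frac < 1.0:
            raise ValidationError(f"split_frac must be in (0, 1), got {self.split_frac}")
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError(f"threshold must be in (0, 1), got {self.threshold}")

    def to_dict(self) -> dict:
        d = {
            "preprocess": dict(vars(self.preprocess)),
            "extractor": dict(vars(self.extractor)),
            "bls": dict(vars(self.bls)),
            "split_frac": self.split_frac,
            "threshold": self.threshold,
            "seed": self.seed,
        }
        d["preprocess"]["shape"] = list(self.preprocess.shape)
        d["extractor"]["conv_widths"] = list(self.extractor.conv_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        pp = dict(d.get("preprocess", {}))
        if "shape" in pp:
            pp["shape"] = tuple(pp["shape"])
        ex = dict(d.get("extractor", {}))
        if "conv_widths" in ex:
            ex["conv_widths"] = tuple(ex["conv_widths"])
        return cls(
            preprocess=PreprocessConfig(**pp),
            extractor=ExtractorConfig(**ex),
            bls=BLSConfig(**d.get("bls", {})),
            split_frac=d.get("split_frac", 0.8),
            threshold=d.get("threshold", 0.5),
            seed=d.get("seed", 0),
        )


@dataclass
class PredictionResult:
    raw_scores: np.ndarray
    probs: np.ndarray
    labels: list[str]


@dataclass
class EBLSModel:
    """Fitted EBLS: blocks, state (A, A+, W), and the label encoding."""

    blocks: list[BLSBlock]
    state: BLSState
    class_codes: list[str]
    config: BLSConfig
    X: np.ndarray  # training features (needed to map new blocks)
    Y: np.ndarray  # one-hot training targets (needed for column updates)
    W_ridge: np.ndarray | None = None  # exact positive-lambda head, if requested

    @property
    def W_effective(self) -> np.ndarray:
        return self.W_ridge if self.W_ridge is not None else self.state.W

    def fingerprint(self) -> str:
        """SHA-256 over the model's defining arrays (for artifact identity)."""
        h = hashlib.sha256()
        for b in self.blocks:
            h.update(np.ascontiguousarray(b.Wf).tobytes())
            h.update(np.ascontiguousarray(b.We).tobytes())
        h.update(np.ascontiguousarray(self.W_effective).tobytes())
        h.update(",".join(self.class_codes).encode())
        return h.hexdigest()


def _one_hot(labels, class_codes: list[str]) -> np.ndarray:
    idx = []
    for l in labels:
        if l not in class_codes:
            raise ValidationError(f"label {l!r} not in class set {class_codes}")
        idx.append(class_codes.index(l))
    Y = np.zeros((len(idx), len(class_codes)))
    Y[np.arange(len(idx)), idx] = 1.0
    return Y


def _class_codes(labels) -> list[str]:
    # class order fixed by first appearance
    seen: list[str] = []
    for l in labels:
        if l not in seen:
            seen.append(l)
    return seen


def _map_all_blocks(X: np.ndarray, blocks: list[BLSBlock]) -> np.ndarray:
    return np.hstack([bls_core.map_block(X, b) for b in blocks])


def _maybe_ridge(model: EBLSModel) -> None:
    if model.config.lam > RIDGE_EXACT_TOL:
        model.W_ridge = bls_core.ridge_solve(model.state.A, model.Y, model.config.lam).W
    else:
        model.W_ridge = None


def fit_ebls(F: FeatureMatrix | np.ndarray, labels, cfg: BLSConfig | None = None) -> EBLSModel:
    """Fit the broad stage: build initial blocks, solve output weights.

    Deterministic under cfg.seed; block ``i`` uses seed ``cfg.seed + 1000*i``.
    """
    cfg = cfg or BLSConfig()
    X = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=np.float64)
    labels = list(labels)
    if X.shape[0] != len(labels):
        raise ValidationError(f"{X.shape[0]} feature rows but {len(labels)} labels")
    class_codes = _class_codes(labels)
    if len(class_codes) < 2:
        raise ValidationError("at least two classes are required")
    Y = _one_hot(labels, class_codes)
    blocks = [
        bls_core.make_block(
            X.shape[1],
            cfg.n_feature_nodes,
            cfg.n_enhance_nodes,
            seed=cfg.seed + 1000 * i,
            shrink=cfg.shrink,
            X=X,
            sae_lam=cfg.sae_lam,
            sae_iters=cfg.sae_iters,
        )
        for i in range(max(cfg.initial_blocks, 1))
    ]
    per_block = cfg.n_feature_nodes + cfg.n_enhance_nodes
    spans = [(i * per_block, (i + 1) * per_block) for i in range(len(blocks))]
    A = _map_all_blocks(X, blocks)
    state = bls_core.build_state(A, Y, lam=cfg.lam, col_spans=spans)
    model = EBLSModel(blocks=blocks, state=state, class_codes=class_codes, config=cfg, X=X, Y=Y)
    _maybe_ridge(model)
    return model


def add_block(m: EBLSModel, F: FeatureMatrix | np.ndarray | None = None) -> EBLSModel:
    """Append one fresh BLS block via the incremental column update.

    Existing blocks' columns are untouched; the new block's seed continues the
    base seed stream. ``F`` defaults to the cached training features.
    """
    X = m.X if F is None else (F.values if isinstance(F, FeatureMatrix) else np.asarray(F))
    if X.shape != m.X.shape or not np.array_equal(X, m.X):
        raise ValidationError("add_block requires the training feature matrix")
    i = len(m.blocks)
    block = bls_core.make_block(
        X.shape[1],
        m.config.n_feature_nodes,
        m.config.n_enhance_nodes,
        seed=m.config.seed + 1000 * i,
        shrink=m.config.shrink,
        X=X,
        sae_lam=m.config.sae_lam,
        sae_iters=m.config.sae_iters,
    )
    H_new = bls_core.map_block(X, block)
    state = bls_core.incremental_add_columns(m.state, H_new, m.Y)
    out = EBLSModel(
        blocks=m.blocks + [block],
        state=state,
        class_codes=m.class_codes,
        config=m.config,
        X=m.X,
        Y=m.Y,
    )
    _maybe_ridge(out)
    return out


def add_samples(m: EBLSModel, F_new: FeatureMatrix | np.ndarray, labels_new) -> EBLSModel:
    """Ingest new studies via the incremental row update (class set is fixed)."""
    X_new = F_new.values if isinstance(F_new, FeatureMatrix) else np.asarray(F_new, dtype=float)
    labels_new = list(labels_new)
    if len(labels_new) == 0:
        return m
    if X_new.shape[1] != m.X.shape[1]:
        raise ValidationError(
            f"new features have {X_new.shape[1]} columns, training had {m.X.shape[1]}"
        )
    Y_new = _one_hot(labels_new, m.class_codes)
    A_new = _map_all_blocks(X_new, m.blocks)
    state = bls_core.incremental_add_rows(m.state, A_new, Y_new)
    out = EBLSModel(
        blocks=m.blocks,
        state=state,
        class_codes=m.class_codes,
        config=m.config,
        X=np.vstack([m.X, X_new]),
        Y=np.vstack([m.Y, Y_new]),
    )
    _maybe_ridge(out)
    return out


def predict(m: EBLSModel, F: FeatureMatrix | np.ndarray) -> PredictionResult:
    """Regression scores -> softmax probabilities -> argmax labels.

    Ties on the maximum probability resolve to the lowest class index (logged).
    """
    X = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain non-finite values")
    A = _map_all_blocks(X, m.blocks)
    raw = A @ m.W_effective
    z = raw - raw.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    top = probs.max(axis=1, keepdims=True)
    if np.any((probs == top).sum(axis=1) > 1):
        logger.warning("tied maximum probabilities; breaking toward the lowest class index")
    labels = [m.class_codes[i] for i in probs.argmax(axis=1)]
    return PredictionResult(raw_scores=raw, probs=probs, labels=labels)


# ---------------------------------------------------------------------------
# Persistence


def save_model(m: EBLSModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=True) as fh:
        fh.attrs["class_codes"] = m.class_codes
        fh.attrs["lam"] = m.config.lam
        fh.attrs["shrink"] = m.config.shrink
        fh.attrs["seed"] = m.config.seed
        fh.attrs["n_feature_nodes"] = m.config.n_feature_nodes
        fh.attrs["n_enhance_nodes"] = m.config.n_enhance_nodes
        fh.attrs["initial_blocks"] = m.config.initial_blocks
        fh.attrs["sae_iters"] = m.config.sae_iters
        fh.attrs["sae_lam"] = m.config.sae_lam
        fh.attrs["col_spans"] = np.asarray(m.state.col_spans, dtype=np.int64)
        fh.create_dataset("W", data=m.state.W, track_times=False)
        fh.create_dataset("A_pinv", data=m.state.A_pinv, track_times=False)
        fh.create_dataset("X", data=m.X, track_times=False)
        fh.create_dataset("Y", data=m.Y, track_times=False)
        if m.W_ridge is not None:
            fh.create_dataset("W_ridge", data=m.W_ridge, track_times=False)
        for i, b in enumerate(m.blocks):
            grp = fh.create_group(f"block_{i}")
            grp.attrs["shrink"] = b.shrink
            grp.attrs["activation"] = b.activation
            grp.attrs["seed"] = b.seed
            grp.create_dataset("Wf", data=b.Wf, track_times=False)
            grp.create_dataset("We", data=b.We, track_times=False)
    return path


def load_model(path: str | Path) -> EBLSModel:
    with h5py.File(path, "r") as fh:
        cfg = BLSConfig(
            n_feature_nodes=int(fh.attrs["n_feature_nodes"]),
            n_enhance_nodes=int(fh.attrs["n_enhance_nodes"]),
            initial_blocks=int(fh.attrs["initial_blocks"]),
            lam=float(fh.attrs["lam"]),
            shrink=float(fh.attrs["shrink"]),
            sae_iters=int(fh.attrs["sae_iters"]),
            sae_lam=float(fh.attrs["sae_lam"]),
            seed=int(fh.attrs["seed"]),
        )
        blocks = []
        i = 0
        while f"block_{i}" in fh:
            grp = fh[f"block_{i}"]
            blocks.append(
                BLSBlock(
                    Wf=grp["Wf"][()],
                    We=grp["We"][()],
                    shrink=float(grp.attrs["shrink"]),
                    activation=str(grp.attrs["activation"]),
                    seed=int(grp.attrs["seed"]),
                )
            )
            i += 1
        X = fh["X"][()]
        Y = fh["Y"][()]
        state = BLSState(
            A=_map_all_blocks(X, blocks),
            A_pinv=fh["A_pinv"][()],
            W=fh["W"][()],
            lam=float(fh.attrs["lam"]),
            col_spans=[tuple(int(x) for x in row) for row in fh.attrs["col_spans"]],
        )
        model = EBLSModel(
            blocks=blocks,
            state=state,
            class_codes=[str(c) for c in fh.attrs["class_codes"]],
            config=cfg,
            X=X,
            Y=Y,
            W_ridge=fh["W_ridge"][()] if "W_ridge" in fh else None,
        )
    return model


# ---------------------------------------------------------------------------
# End-to-end pipeline


def split_manifest(
    manifest: pd.DataFrame, train_frac: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded shuffle of manifest rows, then a train/test split."""
    n = len(manifest)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(n * train_frac))
    return (
        manifest.iloc[order[:n_train]].reset_index(drop=True),
        manifest.iloc[order[n_train:]].reset_index(drop=True),
    )


def _load_groups(manifest: pd.DataFrame, cfg: PipelineConfig, loader):
    """Stream volumes: load -> preprocess -> keep only the slice groups."""
    groups, ids, labels, errors = [], [], [], []
    for row in manifest.itertuples(index=False):
        try:
            vol = loader(row.path)
            groups.append(preprocess_volume(vol, cfg.preprocess))
            ids.append(str(row.study_id))
            labels.append(str(row.label))
        except Exception as exc:
            logger.error("study %s unreadable (%s); skipped", row.study_id, exc)
            errors.append({"study_id": str(row.study_id), "error": str(exc)})
    return groups, ids, labels, errors


def _fit_from_split(
    train_df: pd.DataFrame, cfg: PipelineConfig, loader
) -> tuple[TrainedExtractor, EBLSModel, list[dict]]:
    """Train stage 1 and fit stage 2 from the training split only."""
    groups, ids, labels, errors = _load_groups(train_df, cfg, loader)
    if len(set(labels)) < 2:
        raise ValidationError("training split contains fewer than two classes")
    slices_per_group = groups[0].slices_per_group
    ex_cfg = cfg.extractor
    if ex_cfg.channels_per_group != slices_per_group:
        ex_cfg = ExtractorConfig(**{**vars(ex_cfg), "channels_per_group": slices_per_group})
    extractor = build_extractor(ex_cfg, n_classes=len(set(labels)))
    extractor = slice_cnn.train_extractor(extractor, groups, labels, ex_cfg)
    F_train = slice_cnn.extract_features(extractor, groups, study_ids=ids)
    ebls = fit_ebls(F_train, labels, cfg.bls)
    return extractor, ebls, errors


def build_extractor(cfg: ExtractorConfig, n_classes: int = 3) -> TrainedExtractor:
    return slice_cnn.build_extractor(cfg, n_classes=n_classes)


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    loader=load_volume,
    split: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> dict:
    """Full protocol: shuffle, 80/20 split, train, extract, fit, evaluate.

    ``split`` overrides the seeded shuffle with an explicit
    (train_manifest, test_manifest) pair. Returns a dict with the fitted
    extractor, EBLS model, test report, and written artifact paths.
    """
    cfg = cfg or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, dtype=str)
    if split is None:
        train_df, test_df = split_manifest(manifest, cfg.split_frac, cfg.seed)
    else:
        train_df, test_df = split

    extractor, ebls, errors = _fit_from_split(train_df, cfg, loader)

    test_groups, test_ids, test_labels, test_errors = _load_groups(test_df, cfg, loader)
    F_test = slice_cnn.extract_features(extractor, test_groups, study_ids=test_ids)
    pred = predict(ebls, F_test)
    report = evaluation.build_report(
        np.asarray(test_labels, dtype=object),
        pred.probs,
        ebls.class_codes,
        threshold=cfg.threshold,
    )

    artifacts: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        artifacts["extractor"] = slice_cnn.save_extractor(extractor, out_dir / "extractor.h5")
        artifacts["model"] = save_model(ebls, out_dir / "ebls_model.h5")
        artifacts["features_test"] = slice_cnn.save_features(F_test, out_dir / "features_test.h5")
        artifacts["metrics_csv"] = report.to_csv(out_dir / "metrics.csv")
        report.to_json(out_dir / "metrics.json")
        artifacts["metrics_json"] = out_dir / "metrics.json"
        report.write_roc_csv(out_dir)
        (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
        artifacts["config"] = out_dir / "config.yaml"
        pd.DataFrame({"study_id": train_df["study_id"], "split": "train"}).pipe(
            lambda tr: pd.concat(
                [tr, pd.DataFrame({"study_id": test_df["study_id"], "split": "test"})]
            )
        ).to_csv(out_dir / "split.csv", index=False)

    return {
        "extractor": extractor,
        "model": ebls,
        "report": report,
        "prediction": pred,
        "train_ids": list(train_df["study_id"]),
        "test_ids": test_ids,
        "errors": errors + test_errors,
        "artifacts": artifacts,
    }
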
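"""HMC-LMLP orchestration: per-level training sets, feature augmentation,
sequential level-wise training with early stopping, top-down scoring,
thresholded decoding, and consistency repair.

One MLP is trained per hierarchy level, root-to-deepest, earlier nets frozen.
Four variants differ only in how the input of the level-l net (l ≥ 2) is
built:

* ``Predicted`` — previous level's raw output scores concatenated with the
  original feature vector (training and test);
* ``True`` — previous level's true 0/1 labels during training, previous
  net's scores at test time, concatenated with the features;
* ``NoLabels`` — original features only (no augmentation);
* ``Labels`` — previous level's output scores *only* (features are used at
  level 1 exclusively).

The level-l net is trained on the instances annotated with at least one
level-l class; every test instance traverses every level.  Scores passed
between levels are always the raw sigmoid outputs in [0, 1], never
thresholded.  Final label vectors are obtained by thresholding and
cascading ancestor repair.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataio import EncodedDataset
from .evaluation import MetricReport, au_prc_micro, evaluate_model
from .hierarchy import ClassHierarchy
from .mlp import (LevelNet, TrainHyper, forward_batch, hidden_size, init_net,
                  load_net, save_net, train_epoch)

__all__ = [
    "VARIANTS",
    "DEFAULT_HIDDEN_FRACTIONS",
    "HMCLMLPModel",
    "PredictionResult",
    "select_level_instances",
    "build_level_inputs",
    "train_model",
    "predict_scores",
    "decode",
    "run_replicates",
    "save_model",
    "load_model",
]

VARIANTS = ("Predicted", "True", "NoLabels", "Labels")

#: Hidden-layer widths as fractions of each net's input width, per level.
#: The fraction shrinks with depth because deeper levels have fewer
#: annotated training instances.
DEFAULT_HIDDEN_FRACTIONS = (0.6, 0.5, 0.4, 0.3, 0.2, 0.1)


@dataclass
class LevelLog:
    level: int
    n_instances: int
    epochs_run: int
    best_epoch: int  # 1-based; 0 means the level was skipped
    best_val_auprc: float
    trace: list[float] = field(default_factory=list)  # per-epoch val AU(PRC)


@dataclass
class HMCLMLPModel:
    variant: str
    nets: list[LevelNet | None]  # index l-1 -> net for level l
    hierarchy: ClassHierarchy
    n_features: int
    hidden_fractions: tuple[float, ...] = DEFAULT_HIDDEN_FRACTIONS
    log: list[LevelLog] = field(default_factory=list)

    def hierarchy_hash(self) -> str:
        return hierarchy_hash(self.hierarchy)


@dataclass
class PredictionResult:
    scores: np.ndarray  # (instances × |C|), raw sigmoid outputs
    labels: np.ndarray  # binary, thresholded then consistency-repaired
    threshold: float


def hierarchy_hash(h: ClassHierarchy) -> str:
    return hashlib.sha256("|".join(h.class_ids).encode()).hexdigest()[:16]


def select_level_instances(
    Y: np.ndarray, hierarchy: ClassHierarchy, level: int
) -> np.ndarray:
    """Indices of instances annotated with ≥1 class of the given level.

    With ancestor-closed labels the selected sets are nested across levels;
    at level 1 this is every labeled instance.
    """
    if not 1 <= level <= hierarchy.max_depth:
        raise ValueError(f"level {level} out of range 1..{hierarchy.max_depth}")
    cols = hierarchy.levels[level]
    return np.nonzero(np.asarray(Y)[:, cols].any(axis=1))[0]


def build_level_inputs(
    variant: str,
    level: int,
    X: np.ndarray,
    prev_outputs: np.ndarray | None = None,
    prev_true: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the input matrix for the level-``level`` net.

    The augmentation block (previous-level scores or true labels) comes
    first, then the original features.  ``prev_true`` is only consulted by
    the True variant (training time); at test time True behaves like
    Predicted.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    X = np.asarray(X, dtype=float)
    if level == 1 or variant == "NoLabels":
        return X
    if variant == "True":
        block = prev_true if prev_true is not None else prev_outputs
        if block is None:
            raise ValueError("True variant needs previous-level labels or scores")
        return np.hstack([np.asarray(block, dtype=float), X])
    if prev_outputs is None:
        raise ValueError(f"{variant} variant needs previous-level outputs")
    prev_outputs = np.asarray(prev_outputs, dtype=float)
    if variant == "Labels":
        return prev_outputs
    return np.hstack([prev_outputs, X])  # Predicted


def _level_seeds(seed: int, level: int, max_epochs: int) -> np.ndarray:
    """Deterministic, variant-independent seed stream for one level."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, level])
    return ss.generate_state(max_epochs + 1) % (2**31)


def _scatter(scores_by_level: list[np.ndarray | None],
             hierarchy: ClassHierarchy, n: int) -> np.ndarray:
    full = np.zeros((n, hierarchy.class_count), dtype=float)
    for l, block in enumerate(scores_by_level, start=1):
        if block is not None:
            full[:, hierarchy.levels[l]] = block
    return full


def _forward_levels(
    nets: list[LevelNet | None],
    variant: str,
    X: np.ndarray,
    upto: int | None = None,
) -> list[np.ndarray | None]:
    """Top-down pass: per-level raw score blocks for every instance.

    Skipped (untrained) levels contribute zero scores and a zero
    augmentation block of the proper width for the next level.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    out: list[np.ndarray | None] = []
    prev: np.ndarray | None = None
    limit = len(nets) if upto is None else upto
    for l in range(1, limit + 1):
        net = nets[l - 1]
        inputs = build_level_inputs(variant, l, X, prev_outputs=prev)
        if net is None:
            width = _expected_outputs_of_skipped(nets, l)
            block = np.zeros((n, width), dtype=float)
        else:
            block = forward_batch(net, inputs)
        out.append(block)
        prev = block
    return out


def _expected_outputs_of_skipped(nets, level: int) -> int:
    # width recorded on the model; resolved by train/predict callers that
    # know the hierarchy.  Stored as attribute on the list when training.
    widths = getattr(nets, "level_widths", None)
    if widths is None:
        raise RuntimeError("skipped level without recorded width")
    return widths[level - 1]


class _NetList(list):
    """List of per-level nets that remembers each level's output width."""

    def __init__(self, widths):
        super().__init__()
        self.level_widths = list(widths)


def train_model(
    variant: str,
    train: EncodedDataset,
    valid: EncodedDataset,
    hyper: TrainHyper | None = None,
    hidden_fractions: tuple[float, ...] = DEFAULT_HIDDEN_FRACTIONS,
    patience: int = 10,
    seed: int = 0,
    shuffle: bool = True,
) -> HMCLMLPModel:
    """Train one HMC-LMLP model, level by level, with early stopping.

    After every epoch of the level-l net, the validation AU(PRC) pooled over
    all classes of levels 1..l is computed (frozen previous nets + current
    weights); training of that level stops once the value has not strictly
    improved for ``patience`` consecutive epochs, and the best-scoring
    weights are retained.  Levels with no annotated training instances are
    skipped: their scores are defined as 0.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if train.hierarchy != valid.hierarchy:
        raise ValueError("train and validation hierarchies differ")
    if valid.X.shape[0] == 0:
        raise ValueError("validation split is empty")
    hyper = hyper or TrainHyper()
    h = train.hierarchy
    depth = h.max_depth
    fractions = tuple(hidden_fractions) + (hidden_fractions[-1],) * max(
        0, depth - len(hidden_fractions)
    )
    nets = _NetList(len(h.levels[l]) for l in range(1, depth + 1))
    logs: list[LevelLog] = []

    Xtr, Ytr = train.X, np.asarray(train.Y)
    Yva = np.asarray(valid.Y)
    prev_train_scores: np.ndarray | None = None  # previous level, train set

    for l in range(1, depth + 1):
        cols = h.levels[l]
        idx = select_level_instances(Ytr, h, l)
        seeds = _level_seeds(seed, l, hyper.max_epochs)
        if len(idx) == 0 or len(cols) == 0:
            nets.append(None)
            logs.append(LevelLog(l, 0, 0, 0, float("nan")))
            prev_train_scores = np.zeros((Xtr.shape[0], len(cols)))
            continue

        prev_true = Ytr[:, h.levels[l - 1]] if l >= 2 else None
        inputs_full = build_level_inputs(
            variant, l, Xtr, prev_outputs=prev_train_scores, prev_true=prev_true
        )
        Xl, Yl = inputs_full[idx], Ytr[np.ix_(idx, cols)].astype(float)
        H = hidden_size(fractions[l - 1], Xl.shape[1])
        net = init_net(Xl.shape[1], H, len(cols), hyper.weight_range,
                       seed=int(seeds[0]))
        nets.append(net)

        val_scope = np.concatenate([h.levels[k] for k in range(1, l + 1)])
        best_area = -np.inf
        best_net = net.copy()
        best_epoch = 0
        stale = 0
        trace: list[float] = []
        for epoch in range(1, hyper.max_epochs + 1):
            train_epoch(net, Xl, Yl, hyper, epoch_seed=int(seeds[epoch]),
                        shuffle=shuffle)
            val_blocks = _forward_levels(nets, variant, valid.X, upto=l)
            val_scores = _scatter(val_blocks, h, valid.X.shape[0])
            area = au_prc_micro(val_scores, Yva, h, val_scope)
            trace.append(area)
            if area > best_area:
                best_area = area
                best_net = net.copy()
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
        nets[-1] = best_net
        logs.append(LevelLog(l, len(idx), len(trace), best_epoch,
                             float(best_area), trace))

        # augmentation input for the next level (Predicted/Labels: scores
        # of the frozen best net over *all* training instances)
        blocks = _forward_levels(nets, variant, Xtr, upto=l)
        prev_train_scores = blocks[-1]

    return HMCLMLPModel(
        variant=variant,
        nets=nets,
        hierarchy=h,
        n_features=Xtr.shape[1],
        hidden_fractions=fractions,
        log=logs,
    )


def predict_scores(model: HMCLMLPModel, X: np.ndarray) -> np.ndarray:
    """Raw class scores (instances × |C|) from a top-down pass."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    if not model.nets:
        raise ValueError("model has no trained levels")
    blocks = _forward_levels(model.nets, model.variant, X)
    return _scatter(blocks, model.hierarchy, X.shape[0])


def decode(
    scores: np.ndarray, hierarchy: ClassHierarchy, threshold: float = 0.5
) -> PredictionResult:
    """Threshold scores and repair hierarchy inconsistencies.

    A class is predicted when its score is ≥ threshold; predictions whose
    superclasses were not predicted are then removed, cascading downwards,
    so every returned label row is ancestor-closed.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = hierarchy.repair_consistency((scores >= threshold).astype(np.int8))
    return PredictionResult(scores=scores, labels=labels, threshold=threshold)


def run_replicates(
    variant: str,
    train: EncodedDataset,
    valid: EncodedDataset,
    test: EncodedDataset,
    n_runs: int = 10,
    base_seed: int = 0,
    **train_kwargs,
) -> dict:
    """Independent trainings with seeds base_seed+r; mean ± std per metric."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs: list[MetricReport] = []
    for r in range(n_runs):
        model = train_model(variant, train, valid, seed=base_seed + r,
                            **train_kwargs)
        scores = predict_scores(model, test.X)
        runs.append(evaluate_model(scores, test.Y, test.hierarchy))
    keys = ["au_prc_micro", "auprc_weighted", "auprc_uniform"]
    table = {k: np.array([getattr(rep, k) for rep in runs]) for k in keys}
    return {
        "variant": variant,
        "n_runs": n_runs,
        "per_run": {k: v.tolist() for k, v in table.items()},
        "mean": {k: float(v.mean()) for k, v in table.items()},
        "std": {k: float(v.std(ddof=0)) for k, v in table.items()},
        "reports": runs,
    }


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model: HMCLMLPModel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "variant": model.variant,
        "n_features": model.n_features,
        "hidden_fractions": list(model.hidden_fractions),
        "hierarchy_hash": model.hierarchy_hash(),
        "class_paths": ["/".join(n.path) for n in model.hierarchy.nodes],
        "levels": [
            None if net is None else f"level_{l}.json"
            for l, net in enumerate(model.nets, start=1)
        ],
        "log": [
            {
                "level": e.level, "n_instances": e.n_instances,
                "epochs_run": e.epochs_run, "best_epoch": e.best_epoch,
                "best_val_auprc": e.best_val_auprc, "trace": e.trace,
            }
            for e in model.log
        ],
    }
    for l, net in enumerate(model.nets, start=1):
        if net is not None:
            save_net(net, directory / f"level_{l}.json")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_model(directory: str | Path) -> HMCLMLPModel:
    from .hierarchy import build_hierarchy, parse_label

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    h = build_hierarchy(parse_label(p, "slash") for p in manifest["class_paths"])
    nets = _NetList(len(h.levels[l]) for l in range(1, h.max_depth + 1))
    for entry in manifest["levels"]:
        nets.append(None if entry is None else load_net(directory / entry))
    log = [LevelLog(**e) for e in manifest.get("log", [])]
    return HMCLMLPModel(
        variant=manifest["variant"],
        nets=nets,
        hierarchy=h,
        n_features=manifest["n_features"],
        hidden_fractions=tuple(manifest["hidden_fractions"]),
        log=log,
    )
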
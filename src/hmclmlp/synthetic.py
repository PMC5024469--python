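"""Synthetic tree-structured hierarchical multi-label datasets.

The generator emulates the structure of FunCat-style protein-function
benchmarks: a complete branching-ary class tree up to six levels deep,
multi-path annotations closed under ancestors, class-conditional feature
signal whose per-level informativeness is controlled by a single dependence
knob, optional nominal attributes, and missing values.

Construction: every class gets a feature-space prototype; a child prototype
is its parent's prototype plus a fresh spherical-normal offset scaled by
(1−ρ).  With ρ near 1 siblings are nearly indistinguishable from the
features alone while the parent identity stays informative — exactly the
regime in which augmenting a level's input with the previous level's
predictions should pay off.  Each instance draws 1+Poisson(λ) leaf classes
by independent root-to-leaf walks, its label set is the ancestor closure of
those leaves, and its feature vector is the mean of its leaf prototypes
plus N(0, σ²) noise.  Splits are unstratified seeded thirds
(train/validation/test).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .dataio import Attribute, RawDataset, write_arff_hmc
from .hierarchy import ClassHierarchy, build_hierarchy

__all__ = ["SynthConfig", "SynthDataset", "generate_hierarchy",
           "generate_dataset", "make_fixture", "FIXTURES"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the package's standard dependence
    benchmark (strong parent→child coupling, 3 levels, 2-way branching)."""

    depth: int = 3
    branching: int = 2
    n_instances: int = 900
    n_features: int = 20
    label_intensity: float = 0.5  # λ: extra leaf paths per instance
    noise: float = 0.5            # σ: per-coordinate feature noise
    dependence: float = 0.9       # ρ: parent→child prototype coupling
    missing_rate: float = 0.0
    nominal_count: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.branching < 2:
            raise ValueError("branching must be >= 2")
        if self.n_instances < 3:
            raise ValueError("need at least 3 instances for the three splits")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.label_intensity < 0:
            raise ValueError("label_intensity must be >= 0")
        if self.noise <= 0:
            raise ValueError("noise must be > 0")
        if not 0.0 <= self.dependence <= 1.0:
            raise ValueError("dependence must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.nominal_count < 0 or self.nominal_count > self.n_features:
            raise ValueError("nominal_count must be in [0, n_features]")


@dataclass
class SynthDataset:
    train: RawDataset
    valid: RawDataset
    test: RawDataset
    prototypes: dict[str, np.ndarray]
    config: SynthConfig

    @property
    def hierarchy(self) -> ClassHierarchy:
        return self.train.hierarchy

    def to_arff(self, directory: str | Path, stem: str = "synth") -> dict:
        """Write the Clus-dialect ARFF triple plus a provenance manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for split, data in (("train", self.train), ("valid", self.valid),
                            ("test", self.test)):
            p = directory / f"{stem}.{split}.arff"
            write_arff_hmc(data, p)
            paths[split] = str(p)
        manifest = directory / f"{stem}.manifest.json"
        manifest.write_text(json.dumps({"config": asdict(self.config),
                                        "files": paths}, indent=1))
        paths["manifest"] = str(manifest)
        return paths


def generate_hierarchy(depth: int, branching: int) -> ClassHierarchy:
    """Complete branching-ary class tree: Σ_{l=1..depth} branching^l classes."""
    if depth < 1 or branching < 2:
        raise ValueError("need depth >= 1 and branching >= 2")
    paths: list[tuple[str, ...]] = []

    def grow(prefix: tuple[str, ...]):
        if len(prefix) == depth:
            return
        for b in range(1, branching + 1):
            child = prefix + (str(b),)
            paths.append(child)
            grow(child)

    grow(())
    return build_hierarchy(paths)


def _prototypes(h: ClassHierarchy, p: int, rho: float,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    protos: dict[str, np.ndarray] = {}
    for node in h.nodes:  # lexicographic order: parents precede children
        offset = rng.standard_normal(p)
        if node.parent_id is None:
            protos[node.id] = offset
        else:
            protos[node.id] = protos[node.parent_id] + (1.0 - rho) * offset
    return protos


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Deterministic synthetic train/validation/test triple."""
    rng = np.random.default_rng(cfg.seed)
    h = generate_hierarchy(cfg.depth, cfg.branching)
    protos = _prototypes(h, cfg.n_features, cfg.dependence, rng)

    X = np.empty((cfg.n_instances, cfg.n_features))
    label_sets: list[frozenset[str]] = []
    for i in range(cfg.n_instances):
        k = 1 + rng.poisson(cfg.label_intensity)
        chosen: set[str] = set()
        for _ in range(k):
            path = []
            for _l in range(cfg.depth):
                path.append(str(rng.integers(1, cfg.branching + 1)))
            chosen.add(".".join(path))
        label_sets.append(h.close_labels(chosen))
        mean = np.mean([protos[c] for c in chosen], axis=0)
        X[i] = mean + rng.normal(0.0, cfg.noise, size=cfg.n_features)

    # nominal attributes: tercile-binned copies of the first columns
    attributes: list[Attribute] = []
    rows: list[list[object]] = [[] for _ in range(cfg.n_instances)]
    categories = ("low", "mid", "high")
    for j in range(cfg.n_features):
        col = X[:, j]
        if j < cfg.nominal_count:
            q1, q2 = np.quantile(col, [1 / 3, 2 / 3])
            attributes.append(Attribute(f"f{j}", "nominal", categories))
            binned = np.where(col <= q1, "low",
                              np.where(col <= q2, "mid", "high"))
            for i in range(cfg.n_instances):
                rows[i].append(str(binned[i]))
        else:
            attributes.append(Attribute(f"f{j}", "numeric"))
            for i in range(cfg.n_instances):
                rows[i].append(float(col[i]))

    if cfg.missing_rate > 0:
        mask = rng.random((cfg.n_instances, cfg.n_features)) < cfg.missing_rate
        for i in range(cfg.n_instances):
            for j in range(cfg.n_features):
                if mask[i, j]:
                    rows[i][j] = None

    perm = rng.permutation(cfg.n_instances)
    third = cfg.n_instances // 3
    split_idx = {
        "train": perm[:third],
        "valid": perm[third:2 * third],
        "test": perm[2 * third:],
    }
    vocab = tuple("/".join(n.path) for n in h.nodes)

    def subset(idx: np.ndarray) -> RawDataset:
        return RawDataset(
            attributes=list(attributes),
            rows=[rows[i] for i in idx],
            labels=[label_sets[i] for i in idx],
            hierarchy=h,
            relation="synthetic-hmc",
            class_vocabulary=vocab,
        )

    return SynthDataset(
        train=subset(split_idx["train"]),
        valid=subset(split_idx["valid"]),
        test=subset(split_idx["test"]),
        prototypes=protos,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Tiny deterministic fixtures for unit tests
# ---------------------------------------------------------------------------

def _tiny_2level() -> RawDataset:
    """9 instances, hierarchy {1, 1.2, 2}: |C| = 3, level sizes [2, 1]."""
    h = build_hierarchy([("1", "2"), ("2",)])
    rows = [[float(i), float(i % 3)] for i in range(9)]
    raw = [{"1"}, {"1.2"}, {"2"}, {"1", "2"}, {"1.2", "2"},
           {"1"}, {"1.2"}, {"2"}, {"1.2"}]
    return RawDataset(
        attributes=[Attribute("x0", "numeric"), Attribute("x1", "numeric")],
        rows=rows,
        labels=[h.close_labels(s) for s in raw],
        hierarchy=h,
        relation="tiny-2level",
        class_vocabulary=("1", "1/2", "2"),
    )


def _missing_values() -> RawDataset:
    """Numeric and nominal columns with explicit missing markers."""
    h = build_hierarchy([("1",), ("2",)])
    attrs = [Attribute("num", "numeric"),
             Attribute("col", "nominal", ("a", "b", "c"))]
    rows = [
        [1.0, "a"], [3.0, None], [None, "b"],
        [2.0, "a"], [None, None], [4.0, "c"],
    ]
    labels = [{"1"}, {"2"}, {"1"}, {"2"}, {"1"}, {"2"}]
    return RawDataset(
        attributes=attrs,
        rows=rows,
        labels=[h.close_labels(s) for s in labels],
        hierarchy=h,
        relation="missing-values",
        class_vocabulary=("1", "2"),
    )


def _tie_scores() -> RawDataset:
    """Duplicated feature rows so trained scores collide (threshold ties)."""
    base = _tiny_2level()
    rows = [list(r) for r in base.rows for _ in (0, 1)]
    labels = [l for l in base.labels for _ in (0, 1)]
    return RawDataset(
        attributes=list(base.attributes),
        rows=rows,
        labels=labels,
        hierarchy=base.hierarchy,
        relation="tie-scores",
        class_vocabulary=base.class_vocabulary,
    )


FIXTURES = {
    "tiny-2level": _tiny_2level,
    "missing-values": _missing_values,
    "tie-scores": _tie_scores,
}


def make_fixture(name: str) -> RawDataset:
    """Deterministic hand-checkable datasets used throughout the tests."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}") from None
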
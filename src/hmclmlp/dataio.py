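"""Clus-dialect hierarchical ARFF input/output and dataset preprocessing.

The hierarchical datasets used for protein function prediction ship as ARFF
files with one non-standard attribute::

    @ATTRIBUTE class hierarchical 1,1/2,2/1,...

whose values are slash-separated class paths; an instance carrying several
annotation paths joins them with ``@`` (``1/2@2/1``).  Standard ARFF parsers
reject the ``hierarchical`` type, so this module implements the dialect
directly.  Preprocessing follows the usual neural-network recipe for these
benchmarks: train-split mode/mean imputation, one-attribute-per-value
encoding of nominals with −1 (absence) / +1 (presence), then per-column
standardization to mean 0 and variance 1 using training statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .hierarchy import ClassHierarchy, build_hierarchy, parse_label

__all__ = [
    "Attribute",
    "RawDataset",
    "EncodedDataset",
    "ArffFormatError",
    "read_arff_hmc",
    "write_arff_hmc",
    "impute",
    "encode_nominal",
    "standardize",
    "preprocess_splits",
]

MISSING = None  # in-memory missing marker; "?" on disk


class ArffFormatError(ValueError):
    """Malformed ARFF content; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class Attribute:
    """A declared input attribute: numeric, or nominal with categories."""

    name: str
    kind: str  # "numeric" | "nominal"
    categories: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("numeric", "nominal"):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.kind == "nominal" and not self.categories:
            raise ValueError(f"nominal attribute {self.name!r} has no categories")


@dataclass
class RawDataset:
    """Instances as declared on disk, before any encoding.

    ``rows[i][j]`` is the value of attribute ``j`` for instance ``i``
    (float for numeric, category string for nominal, ``None`` if missing);
    ``labels[i]`` is the ancestor-closed set of class ids.
    """

    attributes: list[Attribute]
    rows: list[list[object]]
    labels: list[frozenset[str]]
    hierarchy: ClassHierarchy
    relation: str = "hmc"
    class_vocabulary: tuple[str, ...] = ()  # declared paths, original order

    @property
    def n_instances(self) -> int:
        return len(self.rows)

    def label_matrix(self) -> np.ndarray:
        return self.hierarchy.labels_to_matrix(self.labels)


@dataclass
class EncodedDataset:
    """Fully numeric view of a :class:`RawDataset`.

    ``X`` is (instances × A) with no missing values once imputation has run;
    ``Y`` is the ancestor-closed binary label matrix over the hierarchy's
    global class ordering.
    """

    X: np.ndarray
    Y: np.ndarray
    feature_names: list[str]
    hierarchy: ClassHierarchy
    stats: dict = field(default_factory=dict)

    @property
    def n_attributes(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# ARFF reading / writing
# ---------------------------------------------------------------------------

def _parse_hier_value(value: str, multilabel_sep: str) -> list[tuple[str, ...]]:
    return [parse_label(part, "slash") for part in value.split(multilabel_sep)]


def read_arff_hmc(
    path: str | Path,
    *,
    multilabel_sep: str = "@",
    hierarchical_keyword: str = "hierarchical",
) -> RawDataset:
    """Read a Clus-dialect hierarchical ARFF file.

    The hierarchy is built from the union of the declared class vocabulary
    and the observed labels; instance label sets are ancestor-closed on load.
    """
    path = Path(path)
    attributes: list[Attribute] = []
    class_vocab: list[tuple[str, ...]] = []
    class_attr_seen = False
    relation = "hmc"
    rows: list[list[object]] = []
    raw_labels: list[list[tuple[str, ...]]] = []
    in_data = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if not in_data:
                upper = line.upper()
                if upper.startswith("@RELATION"):
                    relation = line.split(None, 1)[1] if " " in line else "hmc"
                elif upper.startswith("@ATTRIBUTE"):
                    parts = line.split(None, 2)
                    if len(parts) < 3:
                        raise ArffFormatError("incomplete @ATTRIBUTE", lineno)
                    name, spec = parts[1], parts[2].strip()
                    if spec.lower().startswith(hierarchical_keyword.lower()):
                        if class_attr_seen:
                            raise ArffFormatError(
                                "multiple hierarchical class attributes", lineno
                            )
                        class_attr_seen = True
                        decl = spec[len(hierarchical_keyword):].strip()
                        if decl:
                            class_vocab = [
                                parse_label(tok.strip(), "slash")
                                for tok in decl.split(",")
                                if tok.strip()
                            ]
                    elif spec.lower() in ("numeric", "real", "integer"):
                        attributes.append(Attribute(name, "numeric"))
                    elif spec.startswith("{") and spec.endswith("}"):
                        cats = tuple(c.strip() for c in spec[1:-1].split(","))
                        attributes.append(Attribute(name, "nominal", cats))
                    else:
                        raise ArffFormatError(
                            f"unknown attribute kind {spec!r}", lineno
                        )
                elif upper.startswith("@DATA"):
                    if not class_attr_seen:
                        raise ArffFormatError(
                            "no hierarchical class attribute declared", lineno
                        )
                    in_data = True
                else:
                    raise ArffFormatError(f"unexpected header line {line!r}", lineno)
                continue

            values = [v.strip() for v in line.split(",")]
            if len(values) != len(attributes) + 1:
                raise ArffFormatError(
                    f"expected {len(attributes) + 1} fields, got {len(values)}",
                    lineno,
                )
            row: list[object] = []
            for attr, val in zip(attributes, values[:-1]):
                if val == "?":
                    row.append(MISSING)
                elif attr.kind == "numeric":
                    try:
                        row.append(float(val))
                    except ValueError:
                        raise ArffFormatError(
                            f"bad numeric value {val!r} for {attr.name}", lineno
                        ) from None
                else:
                    if val not in attr.categories:
                        raise ArffFormatError(
                            f"value {val!r} not in categories of {attr.name}",
                            lineno,
                        )
                    row.append(val)
            try:
                paths = _parse_hier_value(values[-1], multilabel_sep)
            except ValueError as exc:
                raise ArffFormatError(str(exc), lineno) from None
            rows.append(row)
            raw_labels.append(paths)

    all_paths = list(class_vocab)
    for paths in raw_labels:
        all_paths.extend(paths)
    hierarchy = build_hierarchy(all_paths)
    labels = [
        hierarchy.close_labels(".".join(p) for p in paths) for paths in raw_labels
    ]
    return RawDataset(
        attributes=attributes,
        rows=rows,
        labels=labels,
        hierarchy=hierarchy,
        relation=relation,
        class_vocabulary=tuple("/".join(p) for p in class_vocab),
    )


def write_arff_hmc(
    dataset: RawDataset,
    path: str | Path,
    *,
    multilabel_sep: str = "@",
) -> Path:
    """Write a :class:`RawDataset` so that :func:`read_arff_hmc` round-trips."""
    path = Path(path)
    vocab = dataset.class_vocabulary or tuple(
        "/".join(n.path) for n in dataset.hierarchy.nodes
    )
    with open(path, "w") as fh:
        fh.write(f"@RELATION {dataset.relation}\n\n")
        for attr in dataset.attributes:
            if attr.kind == "numeric":
                fh.write(f"@ATTRIBUTE {attr.name} numeric\n")
            else:
                fh.write(
                    f"@ATTRIBUTE {attr.name} {{{','.join(attr.categories)}}}\n"
                )
        fh.write(f"@ATTRIBUTE class hierarchical {','.join(vocab)}\n")
        fh.write("\n@DATA\n")
        for row, labels in zip(dataset.rows, dataset.labels):
            fields = [
                "?" if v is MISSING else (repr(v) if isinstance(v, float) else str(v))
                for v in row
            ]
            # most specific classes only; closure restores the rest on load
            leaves = _maximal_labels(dataset.hierarchy, labels)
            fields.append(
                multilabel_sep.join(
                    "/".join(dataset.hierarchy.node(cid).path) for cid in leaves
                )
            )
            fh.write(",".join(fields) + "\n")
    return path


def _maximal_labels(h: ClassHierarchy, labels: frozenset[str]) -> list[str]:
    """Members of a closed set that are not an ancestor of another member."""
    non_maximal = {a.id for cid in labels for a in h.ancestors(cid)}
    return sorted(labels - non_maximal)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def impute(
    dataset: RawDataset, stats_source: RawDataset | None = None
) -> tuple[RawDataset, dict]:
    """Replace missing values by the training split's mode (nominal) / mean
    (numeric).

    ``stats_source`` is the training split; when omitted, the dataset itself
    is the training split.  Nominal imputation happens on category values,
    before any encoding.
    """
    source = stats_source if stats_source is not None else dataset
    fill: dict[str, object] = {}
    for j, attr in enumerate(dataset.attributes):
        observed = [r[j] for r in source.rows if r[j] is not MISSING]
        if not observed:
            raise ValueError(
                f"attribute {attr.name!r} entirely missing in training split"
            )
        if attr.kind == "numeric":
            fill[attr.name] = float(np.mean(observed))
        else:
            # mode; declaration order breaks ties deterministically
            counts = {c: 0 for c in attr.categories}
            for v in observed:
                counts[v] += 1
            fill[attr.name] = max(attr.categories, key=lambda c: counts[c])
    new_rows = [
        [
            fill[attr.name] if v is MISSING else v
            for attr, v in zip(dataset.attributes, row)
        ]
        for row in dataset.rows
    ]
    return replace(dataset, rows=new_rows), fill


def encode_nominal(dataset: RawDataset) -> EncodedDataset:
    """One-attribute-per-value encoding of nominal attributes.

    An attribute with k categories becomes k columns valued −1 (absence) or
    +1 (presence), in declaration order; numeric attributes pass through.
    Missing numeric values become NaN (impute first to avoid them); missing
    nominal values are rejected.
    """
    names: list[str] = []
    columns: list[np.ndarray] = []
    n = dataset.n_instances
    for j, attr in enumerate(dataset.attributes):
        values = [r[j] for r in dataset.rows]
        if attr.kind == "numeric":
            col = np.array(
                [np.nan if v is MISSING else float(v) for v in values], dtype=float
            )
            names.append(attr.name)
            columns.append(col)
        else:
            for v in values:
                if v is MISSING:
                    raise ValueError(
                        f"missing nominal value in {attr.name!r}; impute first"
                    )
                if v not in attr.categories:
                    raise ValueError(
                        f"value {v!r} outside categories of {attr.name!r}"
                    )
            for cat in attr.categories:
                col = np.array(
                    [1.0 if v == cat else -1.0 for v in values], dtype=float
                )
                names.append(f"{attr.name}={cat}")
                columns.append(col)
    X = (
        np.column_stack(columns)
        if columns
        else np.empty((n, 0), dtype=float)
    )
    return EncodedDataset(
        X=X,
        Y=dataset.label_matrix(),
        feature_names=names,
        hierarchy=dataset.hierarchy,
    )


def standardize(
    train: EncodedDataset,
    *others: EncodedDataset,
    sample_variance: bool = False,
) -> list[EncodedDataset]:
    """Standardize all splits with the training split's mean and variance.

    Population (divide-by-m) variance by default; ``sample_variance=True``
    switches to the n−1 form.  Zero-variance columns map to all-zeros.
    """
    if train.X.shape[0] == 0:
        raise ValueError("empty training split")
    mean = train.X.mean(axis=0)
    std = train.X.std(axis=0, ddof=1 if sample_variance else 0)
    safe = np.where(std > 0, std, 1.0)

    def transform(d: EncodedDataset) -> EncodedDataset:
        Z = (d.X - mean) / safe
        Z[:, std == 0] = 0.0
        stats = dict(d.stats)
        stats.update(mean=mean.copy(), std=std.copy())
        return EncodedDataset(
            X=Z,
            Y=d.Y,
            feature_names=list(d.feature_names),
            hierarchy=d.hierarchy,
            stats=stats,
        )

    return [transform(d) for d in (train, *others)]


def preprocess_splits(
    train: RawDataset, *others: RawDataset, sample_variance: bool = False
) -> list[EncodedDataset]:
    """Full pipeline: impute (train stats) → encode nominals → standardize."""
    train_imp, fill = impute(train)
    encoded = [encode_nominal(train_imp)]
    for d in others:
        d_imp, _ = impute(d, stats_source=train)
        encoded.append(encode_nominal(d_imp))
    out = standardize(*encoded, sample_variance=sample_variance)
    for d in out:
        d.stats["imputation"] = fill
    return out
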
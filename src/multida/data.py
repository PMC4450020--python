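"""Domain containers for multiblock data and the block-linkage graph.

A multiblock dataset is an ordered collection of J matrices sharing one
sample set.  The last block is the class block: a single column of +/-1
labels.  Which block pairs contribute correlation terms to the model is
declared by a binary design matrix ``C``; a real weight matrix ``D``
rebalances those contributions (here, up-weighting the expression-class
pair).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MultiblockData",
    "BlockGraph",
    "prepare",
    "default_genomic_graph",
    "DEFAULT_BLOCK_NAMES",
]

DEFAULT_BLOCK_NAMES = ("SNP", "CNV", "DM", "GE", "CLASS")

#: Tokens recognised as the negative (control) class in string labels.
_NEGATIVE_TOKENS = {"control", "ctrl", "normal", "healthy", "wt", "neg", "negative"}


class DimensionError(ValueError):
    """Blocks do not share a common sample dimension."""


class ValidationError(ValueError):
    """Input violates a model contract (e.g. single-class labels)."""


@dataclass
class MultiblockData:
    """Ordered blocks ``X_1 .. X_J`` on one sample set.

    The final block is the class block (one column, values in {-1, +1})
    once :func:`prepare` has run.  ``prepared`` records whether the
    non-class blocks have been column-centered.
    """

    blocks: list[np.ndarray]
    sample_ids: list[str]
    feature_names: list[list[str]]
    block_names: list[str]
    prepared: bool = False
    label_mapping: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def class_index(self) -> int:
        """Index of the class block (always the last block)."""
        return len(self.blocks) - 1

    @property
    def labels(self) -> np.ndarray:
        """The +/-1 class labels (column of the class block)."""
        return self.blocks[self.class_index][:, 0]

    @property
    def shapes(self) -> list[tuple[int, int]]:
        return [b.shape for b in self.blocks]

    def copy(self) -> "MultiblockData":
        return MultiblockData(
            blocks=[b.copy() for b in self.blocks],
            sample_ids=list(self.sample_ids),
            feature_names=[list(f) for f in self.feature_names],
            block_names=list(self.block_names),
            prepared=self.prepared,
            label_mapping=dict(self.label_mapping),
        )

    def validate(self) -> None:
        n = self.n_samples
        for name, b in zip(self.block_names, self.blocks):
            if b.ndim != 2:
                raise DimensionError(f"block {name!r} is not a matrix")
            if b.shape[0] != n:
                raise DimensionError(
                    f"block {name!r} has {b.shape[0]} rows, expected {n}"
                )
        if self.prepared:
            y = self.labels
            if not np.all(np.isin(y, (-1.0, 1.0))):
                raise ValidationError("class block must contain only -1/+1")


def _encode_labels(labels: Sequence) -> tuple[np.ndarray, dict]:
    """Encode a binary label vector as +/-1, returning the mapping used.

    Numeric labels: the larger value is the positive class (so {0,1} and
    {-1,1} map the natural way).  String labels: a recognised control-like
    token is the negative class; otherwise the lexicographically first
    value is positive (``case`` < ``control``).
    """
    arr = np.asarray(labels)
    uniques = sorted(set(arr.tolist()))
    if len(uniques) != 2:
        raise ValidationError(
            f"labels must contain exactly two classes, found {len(uniques)}"
        )
    a, b = uniques
    if all(isinstance(u, (int, float, np.integer, np.floating)) for u in uniques):
        mapping = {a: -1, b: +1}  # larger numeric value is the positive class
    else:
        sa, sb = str(a).lower(), str(b).lower()
        if sb in _NEGATIVE_TOKENS and sa not in _NEGATIVE_TOKENS:
            mapping = {a: +1, b: -1}
        elif sa in _NEGATIVE_TOKENS and sb not in _NEGATIVE_TOKENS:
            mapping = {a: -1, b: +1}
        else:
            mapping = {a: +1, b: -1}
    encoded = np.array([mapping[v] for v in arr.tolist()], dtype=float)
    return encoded, {str(k): int(v) for k, v in mapping.items()}


def prepare(
    raw_blocks: Sequence[np.ndarray],
    labels: Sequence,
    *,
    sample_ids: Sequence[str] | None = None,
    feature_names: Sequence[Sequence[str]] | None = None,
    block_names: Sequence[str] | None = None,
    scale: bool = False,
) -> MultiblockData:
    """Center the feature blocks and attach the +/-1 class block.

    Parameters
    ----------
    raw_blocks
        The J-1 feature matrices (samples x features), sharing row order.
    labels
        Binary class labels, one per sample; encoded to {-1, +1} and
        appended as the final (class) block.
    scale
        If True, additionally divide each column by its standard
        deviation (the model itself only requires zero-mean columns).

    Constant columns are centered to zero and retained (a warning is
    emitted) so feature indices stay aligned with any ground-truth masks.
    Idempotent: preparing already-centered blocks changes nothing.
    """
    blocks = [np.array(b, dtype=float, copy=True) for b in raw_blocks]
    if not blocks:
        raise ValidationError("at least one feature block is required")
    n = blocks[0].shape[0]
    for i, b in enumerate(blocks):
        if b.ndim != 2:
            raise DimensionError(f"block {i} is not a 2-d matrix")
        if b.shape[0] != n:
            raise DimensionError(
                f"block {i} has {b.shape[0]} rows, expected {n} (blocks must "
                "share one sample set)"
            )
    if len(labels) != n:
        raise DimensionError(f"labels have length {len(labels)}, expected {n}")

    y, mapping = _encode_labels(labels)

    for i, b in enumerate(blocks):
        b -= b.mean(axis=0)
        if scale:
            sd = b.std(axis=0, ddof=0)
            nonconst = sd > 0
            b[:, nonconst] /= sd[nonconst]
        const = np.flatnonzero(np.abs(b).max(axis=0) < 1e-12) if b.size else []
        if len(const):
            warnings.warn(
                f"block {i}: {len(const)} constant column(s) centered to zero",
                stacklevel=2,
            )

    blocks.append(y[:, None])
    j_total = len(blocks)

    if block_names is None:
        if j_total == len(DEFAULT_BLOCK_NAMES):
            block_names = list(DEFAULT_BLOCK_NAMES)
        else:
            block_names = [f"block{i + 1}" for i in range(j_total - 1)] + ["CLASS"]
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    if feature_names is None:
        feature_names = [
            [f"{block_names[j]}_{p + 1}" for p in range(blocks[j].shape[1])]
            for j in range(j_total - 1)
        ]
    feature_names = [list(f) for f in feature_names]
    if len(feature_names) == j_total - 1:
        feature_names.append(["label"])

    data = MultiblockData(
        blocks=blocks,
        sample_ids=list(sample_ids),
        feature_names=feature_names,
        block_names=list(block_names),
        prepared=True,
        label_mapping=mapping,
    )
    data.validate()
    return data


@dataclass
class BlockGraph:
    """Block-linkage design matrix ``C`` and correlation weights ``D``.

    ``C`` is binary and symmetric with zero diagonal; ``C[j, k] = 1``
    declares that blocks j and k contribute a squared-covariance term.
    ``D`` carries the same support with real nonnegative weights.
    """

    C: np.ndarray
    D: np.ndarray
    block_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.validate()

    @property
    def n_blocks(self) -> int:
        return self.C.shape[0]

    def validate(self) -> None:
        C, D = self.C, self.D
        if C.shape != D.shape or C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValidationError("C and D must be square matrices of equal shape")
        if not np.array_equal(C, C.T) or not np.array_equal(D, D.T):
            raise ValidationError("C and D must be symmetric")
        if np.any(np.diag(C) != 0) or np.any(np.diag(D) != 0):
            raise ValidationError("C and D must have zero diagonal")
        if not np.all(np.isin(C, (0.0, 1.0))):
            raise ValidationError("C must be binary")
        if np.any(D < 0):
            raise ValidationError("D must be nonnegative")
        if np.any((D > 0) & (C == 0)):
            raise ValidationError("D may only weight pairs linked in C")

    def weights(self, sgcca_mode: bool = False) -> np.ndarray:
        """Weight matrix used in the objective: ``C`` in SGCCA mode, else ``D``."""
        return self.C if sgcca_mode else self.D

    def to_json(self, path) -> None:
        obj = {
            "C": self.C.astype(int).tolist(),
            "D": self.D.tolist(),
            "block_names": self.block_names,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BlockGraph":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            C=np.asarray(obj["C"], dtype=float),
            D=np.asarray(obj["D"], dtype=float),
            block_names=obj.get("block_names"),
        )


def default_genomic_graph() -> BlockGraph:
    """The five-block SNP/CNV/DM/GE/class graph.

    SNP, CNV and DM each link to gene expression (GE), and GE links to the
    class block; the GE-class pair is weighted three times the others so
    the discriminant coupling is not swamped by the larger feature blocks.
    """
    C = np.array(
        [
            [0, 0, 0, 1, 0],
            [0, 0, 0, 1, 0],
            [0, 0, 0, 1, 0],
            [1, 1, 1, 0, 1],
            [0, 0, 0, 1, 0],
        ],
        dtype=float,
    )
    D = C.copy()
    D[3, 4] = D[4, 3] = 3.0
    return BlockGraph(C=C, D=D, block_names=list(DEFAULT_BLOCK_NAMES))
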
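"""Weighted hybrid combination of ranked feature blocks.

Four selected blocks feed the hybrid vector: G (gapped dinucleotide
composition, 5 features), R (reverse-complement composition, 12), P (pseudo
trinucleotide composition, 66) and H (the large selected k-mer block, 425).
Two mixing weights ``a`` and ``lam_mix`` in [0, 1] set each block's
contribution as a take-count

    take(block) = round_half_up(weight * |block|)

with weight ``a`` for G, ``lam_mix`` for R and P, and ``1 - lam_mix`` for H.
The hybrid matrix is the concatenation of each block's top-ranked prefix of
that size (so "+" is ranked-subset concatenation, not vector addition — the
only reading under which the nine catalog groups below have their stated
dimensions).  The nine canonical (a, lam_mix) settings G1..G9 give hybrid
dimensions 425, 78, 430, 83, 428, 252, 255, 81 and 257 at the default block
sizes; G3 (a=1, lam_mix=0) is the strongest configuration in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ParameterError
from .features import FeatureMatrix
from .selection import FeatureRanking

#: the nine cataloged (a, lam_mix) settings
GROUP_WEIGHTS: dict[str, tuple[float, float]] = {
    "G1": (0.0, 0.0),
    "G2": (0.0, 1.0),
    "G3": (1.0, 0.0),
    "G4": (1.0, 1.0),
    "G5": (0.5, 0.0),
    "G6": (0.0, 0.5),
    "G7": (0.5, 0.5),
    "G8": (0.5, 1.0),
    "G9": (1.0, 0.5),
}

BLOCK_ORDER = ("G", "R", "P", "H")


@dataclass(frozen=True)
class BlockSizes:
    """Selected-block sizes feeding the hybrid rule."""

    g: int = 5
    r: int = 12
    p: int = 66
    h: int = 425

    def as_dict(self) -> dict[str, int]:
        return {"G": self.g, "R": self.r, "P": self.p, "H": self.h}


def block_take(block_size: int, weight: float) -> int:
    """Round-half-up(weight * block_size); 0 at weight 0, all at weight 1."""
    if block_size < 0:
        raise ParameterError("block_size must be >= 0")
    if not 0.0 <= weight <= 1.0:
        raise ParameterError(f"weight must be in [0, 1], got {weight}")
    return int(math.floor(weight * block_size + 0.5))


@dataclass(frozen=True)
class HybridSpec:
    """Mixing weights a (G block) and lam_mix (R+P versus H trade-off).

    ``lam_mix`` is the hybrid mixing weight, distinct from the PseTNC
    correlation-tier count which happens to share the symbol in the method's
    original notation.
    """

    a: float = 1.0
    lam_mix: float = 0.0
    block_sizes: BlockSizes = BlockSizes()

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0 or not 0.0 <= self.lam_mix <= 1.0:
            raise ParameterError("a and lam_mix must be in [0, 1]")

    def take_counts(self) -> dict[str, int]:
        sizes = self.block_sizes.as_dict()
        return {
            "G": block_take(sizes["G"], self.a),
            "R": block_take(sizes["R"], self.lam_mix),
            "P": block_take(sizes["P"], self.lam_mix),
            "H": block_take(sizes["H"], 1.0 - self.lam_mix),
        }

    @property
    def dimension(self) -> int:
        return sum(self.take_counts().values())

    @classmethod
    def for_group(cls, name: str, block_sizes: BlockSizes = BlockSizes()) -> "HybridSpec":
        if name not in GROUP_WEIGHTS:
            raise ParameterError(f"unknown group {name!r}; expected G1..G9")
        a, lam = GROUP_WEIGHTS[name]
        return cls(a=a, lam_mix=lam, block_sizes=block_sizes)


@dataclass
class GroupCatalog:
    """The nine canonical hybrid groups with their computed dimensions."""

    specs: dict[str, HybridSpec]

    def dimensions(self) -> dict[str, int]:
        return {name: spec.dimension for name, spec in self.specs.items()}


def catalog_groups(block_sizes: BlockSizes = BlockSizes()) -> GroupCatalog:
    """All nine (a, lam_mix) groups under the given block sizes."""
    return GroupCatalog(
        {name: HybridSpec.for_group(name, block_sizes) for name in GROUP_WEIGHTS}
    )


def build_hybrid(
    blocks: dict[str, FeatureMatrix],
    spec: HybridSpec,
    rankings: dict[str, FeatureRanking] | None = None,
) -> FeatureMatrix:
    """Concatenate ranked block prefixes into one hybrid matrix.

    *blocks* maps tag (G/R/P/H) to a FeatureMatrix whose columns are the
    selected block.  If *rankings* provides a ranking for a tag, its order
    defines the prefix; otherwise the matrix column order is used (i.e. the
    columns are assumed already rank-ordered).  Blocks with a zero take-count
    may be omitted.  All supplied blocks must cover identical samples in
    identical order.  Output columns are provenance-prefixed, e.g.
    ``G:GDC|AA|g0``.
    """
    takes = spec.take_counts()
    ref_ids = None
    parts_names: list[str] = []
    parts_vals = []
    labels = None
    for tag in BLOCK_ORDER:
        n_take = takes[tag]
        if n_take == 0:
            continue
        if tag not in blocks:
            raise AlignmentError(f"block {tag} needed (take={n_take}) but not supplied")
        m = blocks[tag]
        if ref_ids is None:
            ref_ids = m.sample_ids
            labels = m.labels
        elif m.sample_ids != ref_ids:
            raise AlignmentError(f"block {tag} samples differ from other blocks")
        if rankings and tag in rankings:
            order = [n for n in rankings[tag].ordered_names if n in set(m.feature_names)]
            m = m.select_columns(order)
        if n_take > len(m.feature_names):
            raise ParameterError(
                f"block {tag}: take {n_take} exceeds block size {len(m.feature_names)}"
            )
        parts_names.extend(f"{tag}:{n}" for n in m.feature_names[:n_take])
        parts_vals.append(m.values[:, :n_take])
    if ref_ids is None:
        raise ParameterError("hybrid spec takes zero features from every block")
    return FeatureMatrix(
        list(ref_ids), parts_names, np.hstack(parts_vals), "hybrid", labels
    )
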
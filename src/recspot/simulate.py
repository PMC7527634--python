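"""Synthetic two-class DNA datasets with a controllable compositional signal.

The generator emulates a hotspot/coldspot benchmark: two sequence classes of
variable length whose only systematic difference is compositional.  Sequences
are built by concatenating independent trinucleotide draws (trimmed to the
requested length).  Coldspots draw from a background distribution ``q`` over
the 64 trinucleotides, the product of per-base probabilities with an optional
GC shift.  Hotspots draw from

    p(t) = effect / |planted| + (1 - effect) * q(t)   for planted t
    p(t) = (1 - effect) * q(t)                        otherwise,

i.e. an ``effect`` fraction of the probability mass is moved onto a planted
set of trinucleotides, the rest of the background renormalized.  With
``effect = 0`` and ``gc_shift = 0`` the two classes are exchangeable in
distribution.  Generation is deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .sequences import COLDSPOT, HOTSPOT, DnaSequence, SequenceDataset

NUCLEOTIDES = "ACGT"
TRINUCLEOTIDES = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)]


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one synthetic dataset.

    Defaults mirror the benchmark this generator stands in for: 478 hotspot
    and 572 coldspot sequences of 200-3000 nt, with 15% excess trinucleotide
    mass planted on {AAA, TTT} in the hotspot class and no GC shift.
    """

    n_pos: int = 478
    n_neg: int = 572
    length_low: int = 200
    length_high: int = 3000
    effect: float = 0.15
    planted_kmers: tuple[str, ...] = ("AAA", "TTT")
    gc_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect <= 1.0:
            raise ParameterError(f"effect must be in [0, 1], got {self.effect}")
        if not -0.2 <= self.gc_shift <= 0.2:
            raise ParameterError(f"gc_shift must be in [-0.2, 0.2], got {self.gc_shift}")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ParameterError("n_pos and n_neg must be >= 0")
        if self.length_low > self.length_high:
            raise ParameterError("length_low must be <= length_high")
        if self.length_low < 3:
            raise ParameterError("length_low must be >= 3")
        for k in self.planted_kmers:
            if len(k) != 3 or set(k) - set(NUCLEOTIDES):
                raise ParameterError(f"planted k-mer {k!r} is not a trinucleotide")
        if self.effect > 0 and not self.planted_kmers:
            raise ParameterError("effect > 0 requires a nonempty planted set")

    def base_probabilities(self) -> np.ndarray:
        """Per-base probabilities (A, C, G, T) under the GC shift."""
        gc = 0.5 + self.gc_shift
        at = 1.0 - gc
        return np.array([at / 2, gc / 2, gc / 2, at / 2])

    def background_trinucleotide_probs(self) -> np.ndarray:
        """Coldspot distribution over the 64 trinucleotides (products of base probs)."""
        base = self.base_probabilities()
        idx = {c: i for i, c in enumerate(NUCLEOTIDES)}
        return np.array(
            [base[idx[t[0]]] * base[idx[t[1]]] * base[idx[t[2]]] for t in TRINUCLEOTIDES]
        )

    def hotspot_trinucleotide_probs(self) -> np.ndarray:
        """Hotspot distribution: planted mass ``effect`` plus scaled background."""
        p = (1.0 - self.effect) * self.background_trinucleotide_probs()
        if self.effect > 0:
            share = self.effect / len(self.planted_kmers)
            for k in self.planted_kmers:
                p[TRINUCLEOTIDES.index(k)] += share
        return p

    def expected_planted_excess(self) -> float:
        """Expected hotspot-minus-coldspot frequency of the planted set.

        Measured on the generator's own trinucleotide frame (non-overlapping
        triplets): the planted set carries mass effect + (1-effect)*q_planted
        in hotspots versus q_planted in coldspots.
        """
        q = self.background_trinucleotide_probs()
        planted_idx = [TRINUCLEOTIDES.index(k) for k in self.planted_kmers]
        q_planted = float(q[planted_idx].sum())
        return self.effect * (1.0 - q_planted)


def _draw_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    n_tri = -(-length // 3)  # ceil
    draws = rng.choice(64, size=n_tri, p=probs)
    return "".join(TRINUCLEOTIDES[i] for i in draws)[:length]


def generate_synthetic_dataset(spec: SimulationSpec) -> SequenceDataset:
    """Generate a labeled dataset under *spec*; identical spec => identical data."""
    rng = np.random.default_rng(spec.seed)
    p_hot = spec.hotspot_trinucleotide_probs()
    p_cold = spec.background_trinucleotide_probs()
    records: list[DnaSequence] = []
    for i in range(spec.n_pos):
        length = int(rng.integers(spec.length_low, spec.length_high + 1))
        records.append(
            DnaSequence(f"hot{i:04d}", _draw_sequence(rng, length, p_hot), HOTSPOT)
        )
    for i in range(spec.n_neg):
        length = int(rng.integers(spec.length_low, spec.length_high + 1))
        records.append(
            DnaSequence(f"cold{i:04d}", _draw_sequence(rng, length, p_cold), COLDSPOT)
        )
    return SequenceDataset(records)
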
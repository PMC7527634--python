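"""Composition-based sequence encodings.

Four extractors turn a DNA sequence into a fixed-length named feature vector:

* **GDC** (gapped dinucleotide composition): for each gap size kappa (number
  of interposed bases) and each of the 16 ordered nucleotide pairs, the
  fraction of pair positions ``(i, i+kappa+1)`` showing that pair.  Default
  gaps 0..7 give 16 x 8 = 128 features.
* **RCC** (reverse-complement k-mer composition): counts of k-mer windows
  pooled over strand-equivalent (canonical) classes, divided by the sequence
  length L.  Default k in {3, 4, 5} gives 32 + 136 + 512 = 680 features.
* **PseTNC** (pseudo trinucleotide composition): the 64 trinucleotide window
  frequencies augmented with ``lam`` sequence-order correlation factors
  theta_j, each the mean squared physicochemical distance between
  trinucleotides j steps apart, weighted by ``w`` and jointly normalized so
  the whole vector sums to 1.  Default lam = 2 gives 66 features.
* **k-mer bank**: plain k-mer compositions for k = 1..5 (4 + 16 + 64 + 256 +
  1024 = 1364 features, per-k window-normalized).  This is the raw feature
  pool from which the large "H" hybrid block is selected.

Feature-name registries are fixed a priori (every possible name is emitted,
zeros included) so train/test matrices always align.  Sequences too short for
some gap or k yield zeros for those features with a logged warning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SequenceTooShortError, ValidationError
from .sequences import DnaSequence, SequenceDataset, reverse_complement

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"

_ENCODE = np.full(128, -1, dtype=np.int64)
for _i, _c in enumerate(NUCLEOTIDES):
    _ENCODE[ord(_c)] = _i


def _encode(residues: str) -> np.ndarray:
    x = _ENCODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (x < 0).any():
        raise ValidationError("sequence contains characters outside {A,C,G,T}")
    return x


def _kmer_codes(x: np.ndarray, k: int) -> np.ndarray:
    """Rolling base-4 codes of all k-mer windows of an encoded sequence."""
    n = len(x) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + x[j : j + n]
    return codes


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(NUCLEOTIDES[code % 4])
        code //= 4
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k)]


# ---------------------------------------------------------------------------
# canonical (strand-merged) k-mer classes


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement (A<C<G<T).

    Idempotent; merges the two strand readings of the same double-stranded
    word into one class.
    """
    return min(kmer, reverse_complement(kmer))


@lru_cache(maxsize=None)
def _canonical_tables(k: int) -> tuple[tuple[str, ...], np.ndarray]:
    """(sorted canonical class names, code->class-index map of size 4**k)."""
    rc_digit = 3 - np.arange(4)
    n = 4**k
    codes = np.arange(n)
    digits = [(codes // 4**j) % 4 for j in range(k)]  # digits[0] = last base
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        # reverse-complement: complement digits and reverse their order
        rc = rc * 4 + rc_digit[digits[j]]
    canon = np.minimum(codes, rc)
    classes = np.unique(canon)
    class_index = np.searchsorted(classes, canon)
    names = tuple(_decode(int(c), k) for c in classes)
    return names, class_index


def canonical_classes(k: int) -> list[str]:
    """All canonical k-mer classes in lexicographic order (32/136/512 for k=3/4/5)."""
    return list(_canonical_tables(k)[0])


# ---------------------------------------------------------------------------
# feature vector container


@dataclass
class FeatureVector:
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValidationError("names and values lengths differ")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


# ---------------------------------------------------------------------------
# GDC


@dataclass(frozen=True)
class GdcParams:
    """Gap sizes kappa = number of interposed bases; 16 features per gap."""

    gaps: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)

    def __post_init__(self) -> None:
        if len(set(self.gaps)) != len(self.gaps) or any(g < 0 for g in self.gaps):
            raise ParameterError("gaps must be distinct and >= 0")

    @property
    def n_features(self) -> int:
        return 16 * len(self.gaps)

    def feature_names(self) -> list[str]:
        pairs = all_kmers(2)
        return [f"GDC|{p}|g{g}" for g in self.gaps for p in pairs]


def gdc_features(seq: DnaSequence, params: GdcParams = GdcParams()) -> FeatureVector:
    """Gapped dinucleotide composition: observed pair count / pair positions.

    For gap kappa the pair positions are ``(i, i + kappa + 1)`` for
    ``i = 0..L-kappa-2``, i.e. ``L - kappa - 1`` windows.  A gap too large for
    the sequence yields 16 zeros and a warning.
    """
    x = _encode(seq.residues)
    L = len(x)
    values = np.zeros(params.n_features)
    for gi, g in enumerate(params.gaps):
        w = L - g - 1
        if w <= 0:
            logger.warning(
                "record %r (L=%d) too short for gap %d; zero-filling", seq.id, L, g
            )
            continue
        pair = x[:w] * 4 + x[g + 1 : g + 1 + w]
        values[gi * 16 : (gi + 1) * 16] = np.bincount(pair, minlength=16) / w
    if not values.any():
        raise SequenceTooShortError(
            f"record {seq.id!r} too short for every requested gap"
        )
    return FeatureVector(params.feature_names(), values)


# ---------------------------------------------------------------------------
# RCC


@dataclass(frozen=True)
class RccParams:
    """k-mer sizes to pool over canonical classes; default {3,4,5} -> 680 features."""

    ks: tuple[int, ...] = (3, 4, 5)
    normalization: Literal["per-L", "per-window"] = "per-L"

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.ks) or len(set(self.ks)) != len(self.ks):
            raise ParameterError("ks must be distinct and >= 1")

    @property
    def n_features(self) -> int:
        return sum(len(canonical_classes(k)) for k in self.ks)

    def feature_names(self) -> list[str]:
        return [f"RCC|{k}|{c}" for k in self.ks for c in canonical_classes(k)]


def rcc_features(seq: DnaSequence, params: RccParams = RccParams()) -> FeatureVector:
    """Reverse-complement composition: canonical-class window counts / L.

    Division by the full sequence length L (not the window count) is the
    method's defining normalization; ``per-window`` is available as an option.
    Strand-invariant: a sequence and its reverse complement give identical
    vectors.
    """
    x = _encode(seq.residues)
    L = len(x)
    chunks = []
    for k in params.ks:
        names, class_index = _canonical_tables(k)
        codes = _kmer_codes(x, k)
        if len(codes) == 0:
            logger.warning(
                "record %r (L=%d) too short for k=%d; zero-filling", seq.id, L, k
            )
            chunks.append(np.zeros(len(names)))
            continue
        counts = np.bincount(class_index[codes], minlength=len(names))
        denom = L if params.normalization == "per-L" else len(codes)
        chunks.append(counts / denom)
    values = np.concatenate(chunks)
    if not values.any():
        raise SequenceTooShortError(f"record {seq.id!r} too short for every k")
    return FeatureVector(params.feature_names(), values)


# ---------------------------------------------------------------------------
# trinucleotide composition and PseTNC


TNC_NAMES = [f"TNC|{m}" for m in all_kmers(3)]


def tnc_frequencies(seq: DnaSequence) -> FeatureVector:
    """The 64 trinucleotide window frequencies, counts / (L - 2); sums to 1."""
    codes = _kmer_codes(_encode(seq.residues), 3)
    if len(codes) == 0:
        raise SequenceTooShortError(f"record {seq.id!r} shorter than 3")
    return FeatureVector(TNC_NAMES, np.bincount(codes, minlength=64) / len(codes))


def default_property_table(mu: int = 3) -> np.ndarray:
    """A standardized placeholder physicochemical table (64 trinucleotides x mu).

    The three default columns are arbitrary but fixed reproducible values
    (drawn once from a frozen RNG), standardized to mean 0 / variance 1 over
    the 64 trinucleotides.  Any user table of real trinucleotide properties
    (e.g. bendability, stacking energy) can be substituted; the correlation
    machinery only requires standardized columns.
    """
    rng = np.random.default_rng(190534)
    table = rng.standard_normal((64, mu))
    return standardize_property_table(table)


def standardize_property_table(table: np.ndarray) -> np.ndarray:
    """Standardize each property column to mean 0, variance 1 over the 64 rows."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 64:
        raise ParameterError("property table must have shape (64, mu)")
    sd = table.std(axis=0)
    if (sd == 0).any():
        raise ParameterError("property table has a constant column")
    return (table - table.mean(axis=0)) / sd


@dataclass(frozen=True)
class PsetncParams:
    """Pseudo-composition parameters: lam correlation tiers, weight w.

    ``property_table`` maps each trinucleotide (lexicographic order) to mu
    standardized physicochemical values; None selects the built-in
    placeholder table with mu = 3.
    """

    lam: int = 2
    w: float = 0.1
    property_table: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ParameterError("lam must be >= 0")
        if not 0.0 < self.w <= 1.0:
            raise ParameterError("w must be in (0, 1]")
        if self.property_table is not None:
            object.__setattr__(
                self, "property_table", standardize_property_table(self.property_table)
            )

    def table(self) -> np.ndarray:
        return (
            self.property_table
            if self.property_table is not None
            else default_property_table()
        )

    @property
    def n_features(self) -> int:
        return 64 + self.lam

    def feature_names(self) -> list[str]:
        return [f"PseTNC|{m}" for m in all_kmers(3)] + [
            f"PseTNC|theta{j}" for j in range(1, self.lam + 1)
        ]


def theta_correlation(
    seq: DnaSequence, j: int, params: PsetncParams = PsetncParams()
) -> float:
    """Tier-j sequence-order correlation factor.

    With L* = L - 2 trinucleotide positions T_1..T_L*, this is the mean over
    i of the pairwise distance Theta(T_i, T_{i+j}) = (1/mu) * sum_u
    (P_u(T_i) - P_u(T_{i+j}))^2 — the average squared physicochemical
    difference between trinucleotides j steps apart.  Nonnegative; zero on a
    homopolymer.
    """
    codes = _kmer_codes(_encode(seq.residues), 3)
    n = len(codes)
    if not 1 <= j <= n - 1:
        raise ParameterError(f"tier j={j} out of range for L*={n}")
    table = params.table()
    diff = table[codes[:-j]] - table[codes[j:]]
    return float(np.mean(np.mean(diff**2, axis=1)))


def psetnc_features(
    seq: DnaSequence, params: PsetncParams = PsetncParams()
) -> FeatureVector:
    """Pseudo trinucleotide composition: 64 + lam jointly normalized features.

    d_v = f_v / (sum f + w * sum theta) for the 64 composition entries and
    d_{64+j} = w * theta_j / (same denominator) for the lam correlation
    tiers.  All entries nonnegative; the vector sums to exactly 1.  With
    lam = 0 this reduces to the plain trinucleotide frequencies.
    """
    codes = _kmer_codes(_encode(seq.residues), 3)
    n_windows = len(codes)
    if n_windows < params.lam + 1:
        raise SequenceTooShortError(
            f"record {seq.id!r}: L*={n_windows} trinucleotide positions "
            f"cannot support lam={params.lam}"
        )
    f = np.bincount(codes, minlength=64) / n_windows
    thetas = np.array(
        [theta_correlation(seq, j, params) for j in range(1, params.lam + 1)]
    )
    denom = f.sum() + params.w * thetas.sum()
    values = np.concatenate([f, params.w * thetas]) / denom
    return FeatureVector(params.feature_names(), values)


# ---------------------------------------------------------------------------
# k-mer bank (raw pool behind the H hybrid block)


@dataclass(frozen=True)
class BankParams:
    """Plain k-mer compositions for each k; default 1..5 -> 1364 raw features."""

    ks: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.ks) or len(set(self.ks)) != len(self.ks):
            raise ParameterError("ks must be distinct and >= 1")

    @property
    def n_features(self) -> int:
        return sum(4**k for k in self.ks)

    def feature_names(self) -> list[str]:
        return [f"KMER|{k}|{m}" for k in self.ks for m in all_kmers(k)]


def kmer_bank_features(
    seq: DnaSequence, params: BankParams = BankParams()
) -> FeatureVector:
    """Window-normalized k-mer compositions; per-k sums are 1 when L >= k."""
    x = _encode(seq.residues)
    chunks = []
    for k in params.ks:
        codes = _kmer_codes(x, k)
        if len(codes) == 0:
            logger.warning(
                "record %r too short for bank k=%d; zero-filling", seq.id, k
            )
            chunks.append(np.zeros(4**k))
            continue
        chunks.append(np.bincount(codes, minlength=4**k) / len(codes))
    values = np.concatenate(chunks)
    if not values.any():
        raise SequenceTooShortError(f"record {seq.id!r} too short for every bank k")
    return FeatureVector(params.feature_names(), values)


# ---------------------------------------------------------------------------
# dataset-level extraction


BlockTag = Literal["G", "R", "P", "H", "hybrid"]

_METHODS = {
    "gdc": ("G", gdc_features, GdcParams),
    "rcc": ("R", rcc_features, RccParams),
    "psetnc": ("P", psetnc_features, PsetncParams),
    "bank": ("H", kmer_bank_features, BankParams),
}


@dataclass
class FeatureMatrix:
    """Samples x named features, with block provenance and optional labels."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    block_tag: str
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValidationError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("duplicate feature names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            self.sample_ids, list(names), self.values[:, idx], self.block_tag, self.labels
        )

    def subset_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        return FeatureMatrix(
            [self.sample_ids[i] for i in indices],
            self.feature_names,
            self.values[list(indices)],
            self.block_tag,
            [self.labels[i] for i in indices] if self.labels else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "id", self.sample_ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df

    def to_tsv(self, path: str | Path) -> None:
        """Write the TSV dialect: id [label] feature columns, 12 significant digits."""
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path, block_tag: str = "hybrid") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "id":
            raise ValidationError("feature TSV must start with an 'id' column")
        labels = None
        start = 1
        if len(df.columns) > 1 and df.columns[1] == "label":
            labels = df["label"].tolist()
            start = 2
        names = list(df.columns[start:])
        return cls(
            df["id"].astype(str).tolist(),
            names,
            df[names].to_numpy(dtype=float),
            block_tag,
            labels,
        )


def extract_block(
    dataset: SequenceDataset,
    method: Literal["gdc", "rcc", "psetnc", "bank"],
    params=None,
) -> FeatureMatrix:
    """Extract one feature block for every record, rows in dataset order."""
    if method not in _METHODS:
        raise ParameterError(f"unknown method {method!r}")
    if len(dataset) == 0:
        raise ParameterError("dataset is empty")
    tag, fn, params_cls = _METHODS[method]
    if params is None:
        params = params_cls()
    rows, errors = [], []
    names: list[str] = []
    for rec in dataset:
        try:
            vec = fn(rec, params)
        except (SequenceTooShortError, ValidationError) as exc:
            errors.append(str(exc))
            continue
        names = vec.names
        rows.append(vec.values)
    if errors:
        raise ValidationError(
            f"{len(errors)} record(s) failed {method} extraction: " + "; ".join(errors)
        )
    labels = [r.label for r in dataset]
    return FeatureMatrix(
        dataset.ids,
        names,
        np.vstack(rows),
        tag,
        labels if any(l is not None for l in labels) else None,
    )
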
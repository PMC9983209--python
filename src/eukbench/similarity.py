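"""Transcriptome similarity sketches and community diversity metrics.

Bottom-s MinHash sketches over canonical k-mers estimate the Jaccard
similarity between whole transcriptomes; a Mash-distance transform turns
Jaccard into an average nucleotide identity (ANI) estimate, and the >=80%
ANI rule designates "highly related partner" organism pairs. Community
complexity is summarized by richness, the Shannon index, and a composite
score that weights pairwise sketch dissimilarity by the abundance of the
rarer member of each pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .kmers import kmer_codes, splitmix64
from .sequences import SequenceRecord


@dataclass(frozen=True)
class KmerSketch:
    """Bottom-s MinHash sketch: the ``s`` smallest hash values over the
    canonical k-mers of a sequence set."""

    k: int
    sketch_size: int
    hash_seed: int
    hashes: np.ndarray  # sorted uint64, len <= sketch_size
    source_id: str = ""

    def __post_init__(self):
        if self.k < 11:
            raise ValueError("k must be >= 11 for sketching")


def sketch(
    records: Iterable[SequenceRecord] | Iterable[str],
    k: int = 31,
    sketch_size: int = 1000,
    hash_seed: int = 42,
    source_id: str = "",
) -> KmerSketch:
    """Sketch a record collection (or raw sequence strings).

    Canonical k-mers from all records are pooled, hashed with a seeded
    splitmix64, and the ``sketch_size`` smallest distinct hashes retained.
    Raises if no valid k-mer exists (every sequence shorter than k).
    """
    parts = []
    for rec in records:
        seq = rec.seq if isinstance(rec, SequenceRecord) else rec
        codes = kmer_codes(seq, k)
        if codes.size:
            parts.append(codes)
    if not parts:
        raise ValueError(f"no valid {k}-mer in input")
    kmers = np.unique(np.concatenate(parts))
    hashes = np.sort(splitmix64(kmers, seed=hash_seed))
    return KmerSketch(k, sketch_size, hash_seed, hashes[:sketch_size], source_id)


def _check_compatible(a: KmerSketch, b: KmerSketch) -> None:
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    if a.hash_seed != b.hash_seed:
        raise ValueError("hash seed mismatch between sketches")


def jaccard(a: KmerSketch, b: KmerSketch) -> float:
    """MinHash estimate of |A n B| / |A u B| over the merged bottom-s set."""
    _check_compatible(a, b)
    s = min(a.sketch_size, b.sketch_size)
    union = np.union1d(a.hashes, b.hashes)[:s]
    if union.size == 0:
        return 0.0
    inter = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    shared = np.isin(union, inter, assume_unique=True).sum()
    return float(shared / union.size)


class ANIResult(NamedTuple):
    ani: float  # percent in [0, 100]
    below_detection: bool

    def __float__(self) -> float:  # convenience: float(ani_estimate(a, b))
        return self.ani


def ani_from_jaccard(j: float, k: int) -> ANIResult:
    """Mash-distance transform: ANI = 100 * (1 + ln(2j/(1+j)) / k), floored at 0.

    j = 0 is below the sketch's detection limit and reported as 0 with a flag.
    """
    if j <= 0.0:
        return ANIResult(0.0, True)
    if j >= 1.0:
        return ANIResult(100.0, False)
    ani = 100.0 * (1.0 + math.log(2.0 * j / (1.0 + j)) / k)
    return ANIResult(max(ani, 0.0), False)


def ani_estimate(a: KmerSketch, b: KmerSketch) -> ANIResult:
    """ANI (percent) between two sketches via the Mash distance transform."""
    _check_compatible(a, b)
    return ani_from_jaccard(jaccard(a, b), a.k)


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix over community members.

    ``kind`` is ``"jaccard"`` (values in [0,1], diagonal 1) or ``"ani"``
    (percent in [0,100], diagonal 100).
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "jaccard"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        hi = 100.0 if self.kind == "ani" else 1.0
        if v.min() < -1e-9 or v.max() > hi + 1e-9:
            raise ValueError(f"{self.kind} values outside [0, {hi}]")
        self.values = v

    def get(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])


def similarity_matrix(
    sketches: Sequence[KmerSketch], kind: str = "jaccard"
) -> SimilarityMatrix:
    """All-pairs Jaccard or ANI matrix from per-member sketches."""
    n = len(sketches)
    vals = np.zeros((n, n))
    diag = 100.0 if kind == "ani" else 1.0
    for i in range(n):
        vals[i, i] = diag
        for j in range(i + 1, n):
            jac = jaccard(sketches[i], sketches[j])
            v = ani_from_jaccard(jac, sketches[i].k).ani if kind == "ani" else jac
            vals[i, j] = vals[j, i] = v
    return SimilarityMatrix([s.source_id for s in sketches], vals, kind)


def partner_pairs(
    matrix: SimilarityMatrix, threshold_percent: float = 80.0
) -> list[tuple[str, str]]:
    """Unordered pairs of members with ANI >= threshold (percent).

    This is the "highly related partner" rule; the default cutoff is 80%.
    """
    if matrix.kind != "ani":
        raise ValueError("partner detection requires an ANI matrix")
    pairs = []
    for i in range(len(matrix.ids)):
        for j in range(i + 1, len(matrix.ids)):
            if matrix.values[i, j] >= threshold_percent:
                pairs.append((matrix.ids[i], matrix.ids[j]))
    return pairs


@dataclass
class CommunityProportions:
    """Relative abundances p_i of community members; sum to 1."""

    ids: list[str]
    proportions: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if len(p) != len(self.ids):
            raise ValueError("length mismatch between ids and proportions")
        if (p < 0).any():
            raise ValueError("proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {p.sum()}, not 1")
        self.proportions = p


def shannon_index(p: CommunityProportions) -> float:
    """H = -sum p ln p; zero-abundance members contribute 0."""
    q = p.proportions[p.proportions > 0]
    return float(-(q * np.log(q)).sum())


def richness(p: CommunityProportions) -> int:
    """Number of members with nonzero abundance."""
    return int((p.proportions > 0).sum())


def composite_score(matrix: SimilarityMatrix, p: CommunityProportions) -> float:
    """Abundance-weighted dissimilarity: sum_i sum_j (1 - s_ij) * min(p_i, p_j).

    The double sum runs over ordered pairs, so each unordered pair counts
    twice; the diagonal contributes 0 (s_ii = 1). Scores are on [0, 1]
    (use a Jaccard matrix). Zero when all members are identical or when
    the community collapses to a single member.
    """
    if matrix.kind != "jaccard":
        raise ValueError("composite score expects a jaccard matrix")
    if list(matrix.ids) != list(p.ids):
        raise ValueError("matrix and proportions member ids do not match")
    pv = p.proportions
    pmin = np.minimum.outer(pv, pv)
    dissim = 1.0 - matrix.values
    np.fill_diagonal(dissim, 0.0)
    return float((dissim * pmin).sum())
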
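"""Paired-end short-read simulation and sliding-window quality trimming.

Reads are simulated from a designer metatranscriptome: a source contig is
drawn proportional to (expression weight x effective length), a fragment
length is drawn from a truncated normal (default 180 +/- 40 bp, truncated
to [read length, contig length]), the fragment start is uniform, and the
mates are the fragment's 5' end (R1, forward) and 3' end (R2, reverse
complement), 75 bp each by default. Sequencing errors are per-cycle
substitutions at probability 10^(-Q/10) from a per-cycle quality profile;
a cycle with Q >= 60 is treated as error-free.

The trimmer mirrors the classic sliding-window semantics: clip leading and
trailing bases below a quality threshold, cut at the first 4-base window
whose mean quality drops below the threshold, then drop reads shorter than
a minimum length; a dropped mate routes its partner to the unpaired output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .sequences import SequenceRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FragmentModel:
    """Normal fragment-length model truncated to [read_length, contig length]."""

    mean: float = 180.0
    sd: float = 40.0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def sample(
        self, n: int, lower: int, upper: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw n fragment lengths (integers) truncated to [lower, upper]."""
        if self.mean < lower:
            raise ValueError(f"fragment mean {self.mean} below lower bound {lower}")
        if self.sd == 0:
            return np.full(n, int(round(self.mean)))
        a = (lower - self.mean) / self.sd
        b = (upper - self.mean) / self.sd
        draws = truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)
        return np.clip(np.rint(draws).astype(int), lower, upper)


@dataclass(frozen=True)
class QualityProfile:
    """Per-cycle Phred scores; substitution probability is 10^(-Q/10),
    except Q >= 60 which means no errors at that cycle."""

    scores: tuple[int, ...]

    def __post_init__(self):
        if any(q < 2 or q > 60 for q in self.scores):
            raise ValueError("cycle qualities must be in [2, 60]")

    @classmethod
    def linear(cls, read_length: int = 75, q_start: int = 38, q_end: int = 25):
        """Default profile: linear decay from q_start (cycle 1) to q_end."""
        qs = np.rint(np.linspace(q_start, q_end, read_length)).astype(int)
        return cls(tuple(int(q) for q in qs))

    @classmethod
    def error_free(cls, read_length: int = 75):
        return cls((60,) * read_length)

    def error_probs(self) -> np.ndarray:
        q = np.array(self.scores, dtype=float)
        p = 10.0 ** (-q / 10.0)
        p[q >= 60] = 0.0
        return p


def simulate_reads(
    records: Sequence[SequenceRecord],
    weights: Sequence[float],
    n_pairs: int = 1_000_000,
    read_length: int = 75,
    fragment: FragmentModel = FragmentModel(),
    quality: QualityProfile | None = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[SequenceRecord], pd.DataFrame]:
    """Simulate ``n_pairs`` read pairs; returns (R1, R2, truth table).

    Read ids are ``p<index>:<contig>:<start>:<fraglen>`` (0-based fragment
    start); the truth table mirrors them with columns read_id, contig_id,
    start, fragment_length, strand. Deterministic for a fixed seed.
    """
    if quality is None:
        quality = QualityProfile.linear(read_length)
    if len(quality.scores) != read_length:
        raise ValueError("quality profile length != read length")
    if len(records) != len(weights):
        raise ValueError("records and weights differ in length")
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be > 0")
    lengths = np.array([len(r) for r in records])
    short = lengths < read_length
    if short.any():
        bad = records[int(np.nonzero(short)[0][0])].id
        raise ValueError(f"contig {bad} shorter than read length {read_length}")

    rng = np.random.default_rng(seed)
    eff_len = lengths - read_length + 1
    p = w * eff_len
    p = p / p.sum()
    contig_idx = rng.choice(len(records), size=n_pairs, p=p)

    # fragment lengths: drawn per contig (bounds depend on contig length)
    frag_len = np.empty(n_pairs, dtype=int)
    for ci in np.unique(contig_idx):
        mask = contig_idx == ci
        frag_len[mask] = fragment.sample(
            int(mask.sum()), read_length, int(lengths[ci]), rng
        )
    start = rng.integers(0, lengths[contig_idx] - frag_len + 1)

    err_p = quality.error_probs()
    quals = list(quality.scores)

    r1: list[SequenceRecord] = []
    r2: list[SequenceRecord] = []
    rows = []
    chunk = 65536  # substitution masks drawn in chunks to bound memory
    for c0 in range(0, n_pairs, chunk):
        c1 = min(c0 + chunk, n_pairs)
        m = c1 - c0
        err1 = rng.random((m, read_length)) < err_p
        err2 = rng.random((m, read_length)) < err_p
        shift1 = rng.integers(1, 4, size=(m, read_length))
        shift2 = rng.integers(1, 4, size=(m, read_length))
        for i in range(c0, c1):
            ci = int(contig_idx[i])
            s = int(start[i])
            fl = int(frag_len[i])
            frag = records[ci].seq[s : s + fl]
            seq1 = frag[:read_length]
            seq2 = reverse_complement(frag)[:read_length]
            seq1 = _apply_errors(seq1, err1[i - c0], shift1[i - c0])
            seq2 = _apply_errors(seq2, err2[i - c0], shift2[i - c0])
            rid = f"p{i}:{records[ci].id}:{s}:{fl}"
            r1.append(SequenceRecord(rid + "/1", seq1, qual=quals))
            r2.append(SequenceRecord(rid + "/2", seq2, qual=quals))
            rows.append((rid, records[ci].id, s, fl, "+"))
    truth = pd.DataFrame(
        rows, columns=["read_id", "contig_id", "start", "fragment_length", "strand"]
    )
    return r1, r2, truth


def _apply_errors(seq: str, err_mask: np.ndarray, shift: np.ndarray) -> str:
    idx = np.nonzero(err_mask[: len(seq)])[0]
    if idx.size == 0:
        return seq
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = np.full(raw.shape, 0, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    raw[idx] = _BASES[(codes[idx] + shift[idx]) % 4]
    return raw.tobytes().decode("ascii")


@dataclass
class TrimResult:
    r1: list[SequenceRecord]
    r2: list[SequenceRecord]
    unpaired: list[SequenceRecord]
    drop_log: list[tuple[str, str]]  # (read id, reason)


def _trim_one(
    rec: SequenceRecord,
    window: int,
    mean_quality: float,
    leading: int,
    trailing: int,
) -> SequenceRecord:
    q = list(rec.qual)
    lo, hi = 0, len(q)
    while lo < hi and q[lo] < leading:
        lo += 1
    while hi > lo and q[hi - 1] < trailing:
        hi -= 1
    seq, q = rec.seq[lo:hi], q[lo:hi]
    cut = len(q)
    for i in range(0, len(q) - window + 1):
        if sum(q[i : i + window]) / window < mean_quality:
            cut = i
            break
    return SequenceRecord(rec.id, seq[:cut], rec.description, q[:cut])


def trim_reads(
    r1: Sequence[SequenceRecord],
    r2: Sequence[SequenceRecord],
    window: int = 4,
    mean_quality: float = 2.0,
    leading: int = 2,
    trailing: int = 2,
    min_len: int = 50,
) -> TrimResult:
    """Quality-trim a read-pair set; see the module docstring for semantics.

    Raises if the mate files differ in record count.
    """
    if len(r1) != len(r2):
        raise ValueError(f"mate count mismatch: {len(r1)} vs {len(r2)}")
    out = TrimResult([], [], [], [])
    for a, b in zip(r1, r2):
        ta = _trim_one(a, window, mean_quality, leading, trailing)
        tb = _trim_one(b, window, mean_quality, leading, trailing)
        ok_a, ok_b = len(ta) >= min_len, len(tb) >= min_len
        if ok_a and ok_b:
            out.r1.append(ta)
            out.r2.append(tb)
        elif ok_a:
            out.unpaired.append(ta)
            out.drop_log.append((b.id, f"below MINLEN {min_len}"))
        elif ok_b:
            out.unpaired.append(tb)
            out.drop_log.append((a.id, f"below MINLEN {min_len}"))
        else:
            out.drop_log.append((a.id, f"below MINLEN {min_len}"))
            out.drop_log.append((b.id, f"below MINLEN {min_len}"))
    return out
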
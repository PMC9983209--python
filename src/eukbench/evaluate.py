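"""Assembly fidelity evaluation against a designer metatranscriptome.

Covers contig statistics (N50 and friends), six-frame ORF finding,
protein-space recovery at 90% identity / 90% target coverage, a k-mer
pseudo-mapper standing in for quantification ("proxy" percentage mapping
and TPM), taxonomic and functional recovery classification, concordance
statistics (ordinary and through-origin least squares, Welch's t), and
multi-assembler consensus support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .align import local_align
from .cluster import ClusteringParams, greedy_cluster
from .kmers import kmer_set
from .sequences import SequenceRecord, gc_fraction, reverse_complement


# --------------------------------------------------------------------------
# contig statistics


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    min_length: int
    max_length: int
    mean_length: float
    sd_length: float
    n50: int
    gc_fractions: tuple[float, ...] = field(repr=False, default=())


def n50(lengths: Sequence[int]) -> int:
    """Smallest length among the longest contigs that together cover half
    the total assembly length."""
    ls = sorted(lengths, reverse=True)
    half = sum(ls) / 2.0
    acc = 0
    for l in ls:
        acc += l
        if acc >= half:
            return l
    raise ValueError("empty length list")


def assembly_stats(records: Sequence[SequenceRecord]) -> AssemblyStats:
    if not records:
        raise ValueError("no contigs")
    lengths = np.array([len(r) for r in records])
    gcs = tuple(gc_fraction(r.seq) for r in records)
    return AssemblyStats(
        n_contigs=len(records),
        min_length=int(lengths.min()),
        max_length=int(lengths.max()),
        mean_length=float(lengths.mean()),
        sd_length=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        n50=n50(lengths.tolist()),
        gc_fractions=gcs,
    )


# --------------------------------------------------------------------------
# ORF finding (six-frame scan)


@dataclass(frozen=True)
class Orf:
    """An open reading frame; start/end are 0-based half-open nucleotide
    coordinates on the forward strand of the contig."""

    frame: int  # 0..2 on the working strand
    strand: int  # +1 / -1
    start: int
    end: int
    protein: str


def find_orfs(
    contig: str, min_aa: int = 100, require_start: bool = True
) -> list[Orf]:
    """Six-frame ORF scan: stretches from a start codon (or, without
    ``require_start``, from the previous stop) to the next stop codon or
    the end of the frame (open-ended), kept when the protein (stop
    excluded) is at least ``min_aa`` residues. Proteins contain no internal
    stop."""
    L = len(contig)
    out: list[Orf] = []
    for strand, seq in ((1, contig), (-1, reverse_complement(contig))):
        for frame in range(3):
            start_pos: int | None = None if require_start else frame
            i = frame
            while i + 3 <= len(seq):
                codon = seq[i : i + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    if start_pos is not None:
                        _emit(out, seq, strand, frame, start_pos, i + 3, L, min_aa, True)
                    start_pos = None if require_start else i + 3
                elif start_pos is None and codon == "ATG":
                    start_pos = i
                i += 3
            if start_pos is not None and i > start_pos:
                _emit(out, seq, strand, frame, start_pos, i, L, min_aa, False)
    return out


def _emit(out, seq, strand, frame, s, e, L, min_aa, has_stop):
    ncod = (e - s) // 3 - (1 if has_stop else 0)
    if ncod < min_aa:
        return
    prot = str(Seq(seq[s : s + 3 * ncod]).translate())
    if strand == 1:
        start, end = s, e
    else:
        start, end = L - e, L - s
    out.append(Orf(frame, strand, start, end, prot))


# --------------------------------------------------------------------------
# k-mer pseudo-mapping (quantification proxy)


def pseudomap(
    reads: Sequence[SequenceRecord],
    contigs: Sequence[SequenceRecord],
    k: int = 31,
    min_kmer_frac: float = 0.7,
) -> tuple[float, pd.Series, pd.Series]:
    """Assign each read to the contig sharing the most of its canonical
    k-mers, requiring that share to reach ``min_kmer_frac`` of the read's
    k-mers; ties go to the earlier contig. Returns (percent mapped,
    per-contig counts, per-contig TPM). TPM = (count / length in kb)
    normalized to sum 1e6 over contigs with count > 0. This is a proxy for
    read-mapping quantification, not an aligner."""
    if not reads:
        raise ValueError("no reads")
    if k >= min(len(r) for r in reads):
        raise ValueError("k must be smaller than the read length")
    index: dict[int, list[int]] = {}
    for ci, rec in enumerate(contigs):
        for km in kmer_set(rec.seq, k):
            index.setdefault(int(km), []).append(ci)
    counts = np.zeros(len(contigs), dtype=int)
    mapped = 0
    for rec in reads:
        kms = kmer_set(rec.seq, k)
        if kms.size == 0:
            continue
        hits: dict[int, int] = {}
        for km in kms:
            for ci in index.get(int(km), ()):
                hits[ci] = hits.get(ci, 0) + 1
        if not hits:
            continue
        best_ci = min(hits, key=lambda c: (-hits[c], c))
        if hits[best_ci] >= min_kmer_frac * kms.size:
            counts[best_ci] += 1
            mapped += 1
    ids = [c.id for c in contigs]
    counts_s = pd.Series(counts, index=ids, name="count")
    lengths = np.array([len(c) for c in contigs], dtype=float)
    rate = np.where(counts > 0, counts / (lengths / 1000.0), 0.0)
    tpm = rate / rate.sum() * 1e6 if rate.sum() > 0 else rate
    tpm_s = pd.Series(tpm, index=ids, name="tpm")
    return 100.0 * mapped / len(reads), counts_s, tpm_s


# --------------------------------------------------------------------------
# protein-space recovery


@dataclass
class RecoveryReport:
    per_contig: pd.DataFrame  # contig_id, category, matched_designer_ids
    counts: dict[str, int]  # matched / unmatched / no_orf


def _protein_kmers(prot: str, k: int = 6) -> set[str]:
    return {prot[i : i + k] for i in range(len(prot) - k + 1)}


def protein_recovery(
    designer: Sequence[SequenceRecord],
    assembly: Sequence[SequenceRecord],
    min_identity: float = 0.90,
    min_target_coverage: float = 0.90,
    min_aa: int = 100,
    require_start: bool = True,
) -> RecoveryReport:
    """Classify each assembly contig as matched / unmatched / no_orf.

    A contig is matched when at least one of its ORF proteins aligns to a
    designer-contig protein at >= ``min_identity`` identity covering >=
    ``min_target_coverage`` of the designer protein (the designer is the
    target). All matched designer contig ids are recorded.
    """
    designer_prots: list[tuple[str, str]] = []  # (designer contig id, protein)
    pk_index: dict[str, set[int]] = {}
    for rec in designer:
        for orf in find_orfs(rec.seq, min_aa=min_aa, require_start=require_start):
            pi = len(designer_prots)
            designer_prots.append((rec.id, orf.protein))
            for pk in _protein_kmers(orf.protein):
                pk_index.setdefault(pk, set()).add(pi)

    rows = []
    counts = {"matched": 0, "unmatched": 0, "no_orf": 0}
    for rec in assembly:
        orfs = find_orfs(rec.seq, min_aa=min_aa, require_start=require_start)
        if not orfs:
            counts["no_orf"] += 1
            rows.append((rec.id, "no_orf", ""))
            continue
        matched_ids: set[str] = set()
        for orf in orfs:
            cand: set[int] = set()
            for pk in _protein_kmers(orf.protein):
                cand |= pk_index.get(pk, set())
            for pi in sorted(cand):
                did, dprot = designer_prots[pi]
                if did in matched_ids:
                    continue
                res = local_align(orf.protein, dprot)
                if res.identity >= min_identity and res.coverage_b >= min_target_coverage:
                    matched_ids.add(did)
        if matched_ids:
            counts["matched"] += 1
            rows.append((rec.id, "matched", ";".join(sorted(matched_ids))))
        else:
            counts["unmatched"] += 1
            rows.append((rec.id, "unmatched", ""))
    per_contig = pd.DataFrame(
        rows, columns=["contig_id", "category", "matched_designer_ids"]
    )
    return RecoveryReport(per_contig, counts)


# --------------------------------------------------------------------------
# label tables, taxonomic / functional recovery

UNANNOTATED = "unannotated"


@dataclass
class LabelTable:
    """sequence id -> label (genus or function token; ``unannotated`` is an
    explicit value), with optional per-id abundances."""

    labels: dict[str, str]
    abundance: dict[str, float] | None = None

    @classmethod
    def from_tsv(cls, path) -> "LabelTable":
        labels: dict[str, str] = {}
        abund: dict[str, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                cells = line.rstrip("\n").split("\t")
                if lineno == 1 and len(cells) >= 3:
                    try:
                        float(cells[2])
                    except ValueError:
                        continue  # header
                if cells[0] in labels:
                    raise ValueError(f"duplicate id {cells[0]} in {path}")
                labels[cells[0]] = cells[1]
                if len(cells) >= 3:
                    abund[cells[0]] = float(cells[2])
        return cls(labels, abund or None)


@dataclass
class TaxonomicRecovery:
    counts: dict[str, int]  # match / conflict / unannotated
    abundance: dict[str, float]
    per_label: pd.DataFrame  # label, truth_abundance, observed_abundance


def taxonomic_recovery(
    truth: LabelTable,
    observed: LabelTable,
    abundances: Mapping[str, float] | None = None,
) -> TaxonomicRecovery:
    """Classify every observed sequence as match / conflict / unannotated
    against its truth label; sums are abundance-weighted (weight 1 without
    abundances). The per-label table aggregates abundance by label in each
    table, for concordance regression."""
    if abundances is None:
        abundances = {sid: 1.0 for sid in observed.labels}
    missing = set(observed.labels) - set(abundances)
    if missing:
        raise ValueError(f"observed ids without abundance: {sorted(missing)[:3]}")
    counts = {"match": 0, "conflict": 0, "unannotated": 0}
    ab = {"match": 0.0, "conflict": 0.0, "unannotated": 0.0}
    truth_ab: dict[str, float] = {}
    obs_ab: dict[str, float] = {}
    for sid, obs_label in observed.labels.items():
        a = abundances[sid]
        t_label = truth.labels.get(sid, UNANNOTATED)
        if obs_label == UNANNOTATED:
            cat = "unannotated"
        elif obs_label == t_label:
            cat = "match"
        else:
            cat = "conflict"
        counts[cat] += 1
        ab[cat] += a
        if t_label != UNANNOTATED:
            truth_ab[t_label] = truth_ab.get(t_label, 0.0) + a
        if obs_label != UNANNOTATED:
            obs_ab[obs_label] = obs_ab.get(obs_label, 0.0) + a
    labels = sorted(set(truth_ab) | set(obs_ab))
    per_label = pd.DataFrame(
        {
            "label": labels,
            "truth_abundance": [truth_ab.get(l, 0.0) for l in labels],
            "observed_abundance": [obs_ab.get(l, 0.0) for l in labels],
        }
    )
    return TaxonomicRecovery(counts, ab, per_label)


@dataclass
class FunctionalRecovery:
    match: set[str]
    false_positive: set[str]  # present only in the assembly
    not_recovered: set[str]  # present only in the designer
    abundance: dict[str, float]


def functional_recovery(
    designer_labels: LabelTable, assembly_labels: LabelTable
) -> FunctionalRecovery:
    """Compare function-token sets: tokens in both are matches, assembly-only
    tokens are false positives, designer-only tokens were not recovered.
    Abundance totals sum the carrying sequences' abundances (designer
    abundances for match/not_recovered, assembly for false positives)."""

    def token_ab(table: LabelTable) -> dict[str, float]:
        out: dict[str, float] = {}
        for sid, tok in table.labels.items():
            if tok == UNANNOTATED:
                continue
            a = (table.abundance or {}).get(sid, 1.0)
            out[tok] = out.get(tok, 0.0) + a
        return out

    d_ab, a_ab = token_ab(designer_labels), token_ab(assembly_labels)
    match = set(d_ab) & set(a_ab)
    fp = set(a_ab) - set(d_ab)
    nr = set(d_ab) - set(a_ab)
    abundance = {
        "match": sum(d_ab[t] for t in match),
        "false_positive": sum(a_ab[t] for t in fp),
        "not_recovered": sum(d_ab[t] for t in nr),
    }
    return FunctionalRecovery(match, fp, nr, abundance)


# --------------------------------------------------------------------------
# multi-assembler consensus support


def consensus_support(
    assemblies: Mapping[str, Sequence[SequenceRecord]],
    params: ClusteringParams | None = None,
) -> pd.DataFrame:
    """Cluster the union of labeled assemblies and report, per cluster, the
    set of assemblers supporting it and the member length distribution."""
    if len(assemblies) < 2:
        raise ValueError("consensus support needs >= 2 assemblies")
    params = params or ClusteringParams(min_identity=0.98, min_coverage=0.8)
    pool: list[SequenceRecord] = []
    label_of: dict[str, str] = {}
    length_of: dict[str, int] = {}
    for label in assemblies:
        for rec in assemblies[label]:
            rid = f"{label}|{rec.id}"
            pool.append(SequenceRecord(rid, rec.seq, rec.description))
            label_of[rid] = label
            length_of[rid] = len(rec)
    clusters = greedy_cluster(pool, params)
    rows = []
    for c in clusters:
        mids = c.member_ids()
        labels = sorted({label_of[m] for m in mids})
        lens = [length_of[m] for m in mids]
        rows.append(
            (c.representative, len(labels), ",".join(labels), len(mids),
             min(lens), max(lens), float(np.mean(lens)))
        )
    return pd.DataFrame(
        rows,
        columns=["representative", "support", "assemblers", "n_members",
                 "min_length", "max_length", "mean_length"],
    )


# --------------------------------------------------------------------------
# concordance statistics


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float


def linear_regression(
    x: Sequence[float], y: Sequence[float], through_origin: bool = False
) -> RegressionResult:
    """Ordinary least squares of y on x; with ``through_origin`` the
    intercept is forced to 0 and the slope is sum(xy)/sum(x^2). Requires
    >= 3 points and non-constant x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    if through_origin:
        slope = float((x * y).sum() / (x * x).sum())
        intercept = 0.0
    else:
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = float(sxy / sxx)
        intercept = float(y.mean() - slope * x.mean())
    if np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return RegressionResult(slope, intercept, r, r * r)


def welch_t(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's two-sample t test: (t, Welch-Satterthwaite df, two-sided p).

    Two zero-variance samples with equal means return t = 0 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
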
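"""Greedy sequence clustering and the multi-assembler merge hierarchy.

Clustering is greedy-incremental in the linclust style: sequences are
visited longest first (ties broken by id), and each either joins the first
existing cluster whose representative it matches at both an identity and a
coverage threshold, or founds a new cluster. A shared canonical 15-mer
prefilter prunes the representatives actually aligned against. Because
representatives are visited in founding order and all ordering rules are
deterministic, the output is invariant to input record order.

The merge hierarchy consolidates multi-assembler outputs:

* ``merge_assemblies`` concatenates one sample's assemblies (AGM),
  relabeling contigs with group and assembler provenance;
* ``dedup_identical`` removes contigs fully contained in a longer contig at
  100% identity (100% of the shorter sequence aligned);
* ``build_cag`` clusters the deduplicated set at 98% identity;
* ``build_mad`` concatenates every sample's CAG (SWAM) and clusters the
  union at 98% identity into the final cross-sample assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import local_align
from .kmers import kmer_set
from .sequences import SequenceRecord

PREFILTER_K = 15


@dataclass(frozen=True)
class ClusteringParams:
    """Thresholds for membership against a cluster representative.

    ``coverage_mode`` picks whose span the coverage threshold applies to:
    the shorter of the two sequences, or the target (representative).
    """

    min_identity: float = 0.98
    min_coverage: float = 0.8
    coverage_mode: str = "shorter_sequence"
    strand_aware: bool = True
    alphabet: str = "nucleotide"

    def __post_init__(self):
        if not (0 < self.min_identity <= 1) or not (0 < self.min_coverage <= 1):
            raise ValueError("thresholds must be in (0, 1]")
        if self.coverage_mode not in ("shorter_sequence", "target_sequence"):
            raise ValueError(f"unknown coverage_mode {self.coverage_mode!r}")
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")


@dataclass
class Cluster:
    """A representative plus its members with identity/coverage to it."""

    representative: str
    members: list[tuple[str, float, float]]  # (member id, identity, coverage)

    def member_ids(self) -> list[str]:
        return [m[0] for m in self.members]


def _membership(member: SequenceRecord, rep: SequenceRecord, params: ClusteringParams):
    """(passes, identity, coverage) of ``member`` against ``rep``."""
    res = local_align(
        member.seq, rep.seq, strand_aware=params.strand_aware and params.alphabet == "nucleotide"
    )
    if params.coverage_mode == "target_sequence":
        cov = res.coverage_b
    else:
        cov = res.coverage_a if len(member) <= len(rep) else res.coverage_b
    ok = res.identity >= params.min_identity and cov >= params.min_coverage
    return ok, res.identity, cov


def greedy_cluster(
    records: Sequence[SequenceRecord], params: ClusteringParams
) -> list[Cluster]:
    """Greedy incremental clustering; see module docstring for the scheme."""
    if not records:
        raise ValueError("no records to cluster")
    order = sorted(records, key=lambda r: (-len(r), r.id))
    canonical = params.alphabet == "nucleotide"
    clusters: list[Cluster] = []
    reps: list[SequenceRecord] = []
    kmer_index: dict[int, list[int]] = {}  # prefilter k-mer -> rep positions
    for rec in order:
        kms = kmer_set(rec.seq, PREFILTER_K, canonical=canonical)
        cand = set()
        for km in kms:
            cand.update(kmer_index.get(int(km), ()))
        placed = False
        for ci in sorted(cand):  # founding order
            ok, ident, cov = _membership(rec, reps[ci], params)
            if ok:
                clusters[ci].members.append((rec.id, ident, cov))
                placed = True
                break
        if not placed:
            ci = len(clusters)
            clusters.append(Cluster(rec.id, [(rec.id, 1.0, 1.0)]))
            reps.append(rec)
            for km in kms:
                kmer_index.setdefault(int(km), []).append(ci)
    return clusters


def clusters_table(clusters: Iterable[Cluster]) -> pd.DataFrame:
    rows = [
        (m, c.representative, ident, cov)
        for c in clusters
        for (m, ident, cov) in c.members
    ]
    return pd.DataFrame(rows, columns=["member", "representative", "identity", "coverage"])


def _representatives(
    records: Sequence[SequenceRecord], clusters: list[Cluster]
) -> list[SequenceRecord]:
    by_id = {r.id: r for r in records}
    return [by_id[c.representative] for c in clusters]


def merge_assemblies(
    assemblies: Mapping[str, Sequence[SequenceRecord]], group: str
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Concatenate one assembly group's assemblies into an AGM.

    ``assemblies`` maps assembler label -> records. Contigs are renamed
    ``<group>_<assembler>_<original id>``; a provenance table maps new ids
    back. Raises on an id collision after rewriting.
    """
    if not assemblies:
        raise ValueError("no assemblies to merge")
    out: list[SequenceRecord] = []
    rows = []
    seen: set[str] = set()
    for label in assemblies:
        for rec in assemblies[label]:
            new_id = f"{group}_{label}_{rec.id}"
            if new_id in seen:
                raise ValueError(f"id collision after rewrite: {new_id}")
            seen.add(new_id)
            out.append(SequenceRecord(new_id, rec.seq, rec.description))
            rows.append((new_id, group, label, rec.id))
    prov = pd.DataFrame(rows, columns=["contig_id", "group", "assembler", "original_id"])
    return out, prov


def dedup_identical(agm: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Remove contigs contained at 100% identity over the full shorter
    sequence in a longer retained contig (first consolidation round)."""
    params = ClusteringParams(
        min_identity=1.0, min_coverage=1.0, coverage_mode="shorter_sequence"
    )
    clusters = greedy_cluster(agm, params)
    return _representatives(agm, clusters)


def build_cag(
    deduped: Sequence[SequenceRecord], min_identity: float = 0.98, min_coverage: float = 0.8
) -> tuple[list[SequenceRecord], list[Cluster]]:
    """Second consolidation round: cluster at 98% identity (sequencing-error
    tolerance); returns (CAG records, clusters)."""
    params = ClusteringParams(min_identity=min_identity, min_coverage=min_coverage)
    clusters = greedy_cluster(deduped, params)
    return _representatives(deduped, clusters), clusters


def build_mad(
    cags: Sequence[Sequence[SequenceRecord]],
    min_identity: float = 0.98,
    min_coverage: float = 0.8,
) -> tuple[list[SequenceRecord], list[Cluster]]:
    """Cross-sample consolidation: concatenate all CAGs (SWAM) and cluster
    the union at 98% identity; returns (MAD records, clusters)."""
    if not cags:
        raise ValueError("no CAGs supplied")
    swam = [rec for cag in cags for rec in cag]
    params = ClusteringParams(min_identity=min_identity, min_coverage=min_coverage)
    clusters = greedy_cluster(swam, params)
    return _representatives(swam, clusters), clusters
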
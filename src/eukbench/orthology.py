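"""Orthogroup tables: loading/writing the OrthoFinder TSV dialect, inferring
approximate orthogroups from sequences, and picking out single-copy groups.

The TSV dialect is ``Orthogroup<TAB>org1<TAB>org2...`` with cells holding
comma-space separated gene lists and empty cells meaning absent. Inference
is a single-linkage closure over pairwise local alignments passing both an
identity and a coverage threshold — an approximation that recovers the true
partition when within-family divergence is modest and families are well
separated, which is the regime the synthetic panels are built in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .align import local_align
from .kmers import kmer_set
from .sequences import SequenceRecord


@dataclass
class OrthogroupTable:
    """orthogroup id -> {organism id -> gene ids}, plus the organism roster."""

    groups: dict[str, dict[str, list[str]]]
    organisms: list[str]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for og, per_org in self.groups.items():
            for org, genes in per_org.items():
                if org not in self.organisms:
                    raise ValueError(f"organism {org} not in roster")
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene {g} appears in both {seen[g]} and {og}"
                        )
                    seen[g] = og

    def gene_to_group(self) -> dict[str, str]:
        return {
            g: og
            for og, per_org in self.groups.items()
            for genes in per_org.values()
            for g in genes
        }

    def n_genes(self) -> int:
        return sum(
            len(genes) for per_org in self.groups.values() for genes in per_org.values()
        )


def load_orthogroups(path) -> OrthogroupTable:
    """Parse an Orthogroups.tsv-dialect table.

    Raises if a gene id occurs in more than one row (the error names the
    gene) or the header is missing.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty orthogroup table")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0].lower() not in ("orthogroup", "og"):
        raise ValueError(f"{path}: missing 'Orthogroup' header")
    organisms = header[1:]
    groups: dict[str, dict[str, list[str]]] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        og = cells[0]
        per_org: dict[str, list[str]] = {}
        for org, cell in zip(organisms, cells[1:]):
            genes = [g.strip() for g in cell.split(",") if g.strip()]
            if genes:
                per_org[org] = genes
        groups[og] = per_org
    return OrthogroupTable(groups, organisms)


def write_orthogroups(table: OrthogroupTable, path) -> None:
    """Write the table back in the same TSV dialect (deterministic order)."""
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.organisms) + "\n")
        for og in sorted(table.groups):
            per_org = table.groups[og]
            cells = [", ".join(per_org.get(org, [])) for org in table.organisms]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def infer_orthogroups(
    transcripts: Mapping[str, Sequence[SequenceRecord]],
    min_identity: float = 0.80,
    min_coverage: float = 0.50,
    alphabet: str = "nucleotide",
    prefilter_k: int = 15,
) -> OrthogroupTable:
    """Approximate orthogroups by single-linkage over pairwise alignments.

    Two genes are linked when their best local alignment (both strands for
    nucleotides) reaches ``min_identity`` with at least ``min_coverage`` of
    the shorter sequence aligned. Candidate pairs must share >=1 canonical
    ``prefilter_k``-mer, which prunes the quadratic comparison to near-
    homologous pairs. Groups are numbered OG0000000... ordered by their
    lexicographically smallest gene id, so output is independent of input
    order.
    """
    if not transcripts:
        raise ValueError("no organisms supplied")
    if not (0 < min_identity <= 1) or not (0 < min_coverage <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    genes: list[tuple[str, str, str]] = []  # (gene id, organism, seq)
    for org in sorted(transcripts):
        for rec in transcripts[org]:
            genes.append((rec.id, org, rec.seq))
    if not genes:
        raise ValueError("no genes supplied")
    genes.sort(key=lambda t: t[0])

    parent = list(range(len(genes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # shared k-mer prefilter -> candidate pairs
    kmer_index: dict[int, list[int]] = {}
    strand = alphabet == "nucleotide"
    for idx, (_, _, seq) in enumerate(genes):
        for km in kmer_set(seq, prefilter_k, canonical=strand):
            kmer_index.setdefault(int(km), []).append(idx)
    candidates = set()
    for hits in kmer_index.values():
        for x in range(len(hits)):
            for y in range(x + 1, len(hits)):
                candidates.add((hits[x], hits[y]))

    for i, j in sorted(candidates):
        if find(i) == find(j):
            continue
        res = local_align(genes[i][2], genes[j][2], strand_aware=strand)
        shorter_cov = (
            res.coverage_a
            if len(genes[i][2]) <= len(genes[j][2])
            else res.coverage_b
        )
        if res.identity >= min_identity and shorter_cov >= min_coverage:
            union(i, j)

    components: dict[int, list[int]] = {}
    for idx in range(len(genes)):
        components.setdefault(find(idx), []).append(idx)
    groups: dict[str, dict[str, list[str]]] = {}
    for gi, root in enumerate(sorted(components)):
        per_org: dict[str, list[str]] = {}
        for idx in components[root]:
            gid, org, _ = genes[idx]
            per_org.setdefault(org, []).append(gid)
        groups[f"OG{gi:07d}"] = per_org
    return OrthogroupTable(groups, sorted(transcripts))


def single_copy_groups(
    table: OrthogroupTable, roster: Sequence[str] | None = None
) -> set[str]:
    """Orthogroups with exactly one gene for every roster member.

    The roster defaults to the table's full organism list; evaluating
    against a community roster restricts "every organism" to the community.
    """
    roster = list(roster) if roster is not None else list(table.organisms)
    missing = set(roster) - set(table.organisms)
    if missing:
        raise ValueError(f"roster organisms not in table: {sorted(missing)}")
    out = set()
    for og, per_org in table.groups.items():
        if all(len(per_org.get(org, [])) == 1 for org in roster):
            out.add(og)
    return out
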
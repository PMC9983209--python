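"""Synthetic reference transcriptome panels with known ground truth.

The generator emulates a panel of marine microbial eukaryote reference
transcriptomes: several organisms, gene families shared across subsets of
them at controlled nucleotide divergence, designated strain pairs that are
nearly identical, single-copy gene families present once in every
organism, and taxonomy / function labels for every gene family. Because
the orthology, divergence and labels are constructed rather than inferred,
every downstream stage (similarity, orthogroup inference, community
design, read simulation, recovery evaluation) can be tested against exact
truth without downloading any reference data. Real reference FASTAs can be
substituted wherever a panel is consumed.

Family model: star topology — each family has one ancestral sequence and
every member is an independently mutated copy (substitutions uniform over
the three alternative bases). A strain partner instead mirrors its
partner's genes at the (low) strain-pair rate. Ancestral genes are built
as a single open reading frame (ATG, non-stop codons, terminal stop) so
ORF-based protein recovery is meaningful on designer contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .orthology import OrthogroupTable, write_orthogroups
from .sequences import SequenceRecord, write_sequences

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class Organism:
    id: str
    genus: str
    species: str
    strain: str


@dataclass(frozen=True)
class PanelConfig:
    """Knobs of the synthetic panel generator.

    Rates are per-base substitution probabilities. ``within_family_sub_rate``
    applies per member relative to the family ancestor (so two members of a
    family are roughly twice that far apart); the default 0.15 puts
    cross-organism orthologs near 70-75% nucleotide identity, the regime of
    real cross-genus ortholog pairs, which keeps whole-transcriptome ANI
    between non-strain organisms below the 80% partner cutoff.
    ``strain_pair_sub_rate`` applies between the two genomes of a
    designated strain pair (default 2%, i.e. ~98% ANI strains).
    ``fraction_single_copy`` is the fraction of each organism's genes placed
    in single-copy all-member families; ``fraction_shared_families`` is the
    fraction of the remaining genes placed in families shared with other
    organisms. A strain partner mirrors all of its partner's single-copy and
    shared families plus ``strain_exclusive_mirror`` of its exclusive ones.
    """

    n_organisms: int = 12
    genes_per_organism: int = 50
    gene_length: tuple[int, int] = (300, 3000)
    fraction_shared_families: float = 0.5
    within_family_sub_rate: float = 0.15
    strain_pair_sub_rate: float = 0.02
    fraction_single_copy: float = 0.1
    n_strain_pairs: int = 1
    strain_exclusive_mirror: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_organisms < 1 or self.genes_per_organism < 1:
            raise ValueError("counts must be >= 1")
        for r in (
            self.fraction_shared_families,
            self.within_family_sub_rate,
            self.strain_pair_sub_rate,
            self.fraction_single_copy,
            self.strain_exclusive_mirror,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if 2 * self.n_strain_pairs > self.n_organisms:
            raise ValueError("more strain-pair members than organisms")
        if self.gene_length[0] < 30 or self.gene_length[1] < self.gene_length[0]:
            raise ValueError("invalid gene length range")


@dataclass
class ReferencePanel:
    """A set of organism transcriptomes plus their ground truth."""

    organisms: list[Organism]
    transcripts: dict[str, list[SequenceRecord]]
    truth_orthogroups: OrthogroupTable
    strain_pairs: list[tuple[str, str]]
    function_labels: dict[str, str]
    config: PanelConfig | None = None

    def __post_init__(self):
        ids = {o.id for o in self.organisms}
        for a, b in self.strain_pairs:
            if a not in ids or b not in ids:
                raise ValueError(f"strain pair ({a}, {b}) references unknown organism")
        missing = set(self.truth_orthogroups.groups) - set(self.function_labels)
        if missing:
            raise ValueError(f"orthogroups without function labels: {sorted(missing)[:3]}")

    def organism_ids(self) -> list[str]:
        return [o.id for o in self.organisms]

    def record(self, gene_id: str) -> SequenceRecord:
        org = gene_id.rsplit("_g", 1)[0]
        for rec in self.transcripts[org]:
            if rec.id == gene_id:
                return rec
        raise KeyError(gene_id)


def mutate_sequence(
    seq: str,
    sub_rate: float,
    indel_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Mutate a sequence: independent per-base substitutions (uniform over
    the 3 alternative bases) at ``sub_rate``, then insertions/deletions at
    ``indel_rate`` per position (50/50 ins vs del). Deterministic for a
    fixed seed. Raises on an empty sequence.
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if not (0.0 <= sub_rate <= 1.0 and 0.0 <= indel_rate < 1.0):
        raise ValueError("rates must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.shape, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    out = raw.copy()
    if sub_rate > 0:
        hit = rng.random(len(seq)) < sub_rate
        idx = np.nonzero(hit)[0]
        if idx.size:
            shift = rng.integers(1, 4, size=idx.size)
            newcode = (codes[idx] + shift) % 4
            # N positions get a uniform random base (always a change)
            n_mask = codes[idx] < 0
            if n_mask.any():
                newcode[n_mask] = rng.integers(0, 4, size=int(n_mask.sum()))
            out[idx] = _BASES[newcode]
    if indel_rate > 0:
        events = rng.random(len(out)) < indel_rate
        is_ins = rng.random(len(out)) < 0.5
        ins_base = _BASES[rng.integers(0, 4, size=len(out))]
        pieces = []
        for i, b in enumerate(out):
            if events[i]:
                if is_ins[i]:
                    pieces.append(ins_base[i])
                    pieces.append(b)
                # deletion: skip the base
            else:
                pieces.append(b)
        out = np.array(pieces, dtype=np.uint8)
    return out.tobytes().decode("ascii")


def _repair_frame(seq: str) -> str:
    """Restore an open frame after neutral mutation: put back the start
    codon and terminal stop, and recode internal in-frame stops (T -> C in
    the first codon position, yielding CAA/CAG/CGA). Real orthologs keep
    their frame under purifying selection; the neutral mutation model does
    not, so family members are repaired to stay ORF-bearing."""
    n_codons = len(seq) // 3
    codons = [seq[3 * i : 3 * i + 3] for i in range(n_codons)]
    tail = seq[3 * n_codons :]
    codons[0] = "ATG"
    for i in range(1, n_codons - 1):
        if codons[i] in _STOPS:
            codons[i] = "C" + codons[i][1:]
    if codons[-1] not in _STOPS:
        codons[-1] = "TAA"
    return "".join(codons) + tail


def _random_orf(rng: np.random.Generator, lo: int, hi: int) -> str:
    """One open reading frame: ATG + random non-stop codons + stop."""
    length = int(rng.integers(lo, hi + 1))
    n_codons = max(length // 3, 4)
    body = rng.integers(0, len(_CODONS), size=n_codons - 2)
    stop = _STOPS[int(rng.integers(0, 3))]
    return "ATG" + "".join(_CODONS[i] for i in body) + stop


def generate_panel(config: PanelConfig) -> ReferencePanel:
    """Build a panel from a config; byte-identical output for a fixed seed.

    Raises if the per-organism gene budget cannot host the required
    single-copy families.
    """
    rng_layout = np.random.default_rng([config.seed, 0])
    rng_seq = np.random.default_rng([config.seed, 1])

    n = config.n_organisms
    org_ids = [f"org{i + 1:02d}" for i in range(n)]
    pairs = [(org_ids[2 * i], org_ids[2 * i + 1]) for i in range(config.n_strain_pairs)]
    mirror_of = {b: a for a, b in pairs}
    base_orgs = [o for o in org_ids if o not in mirror_of]

    organisms = []
    for i, oid in enumerate(org_ids):
        partner_first = next((a for a, b in pairs if b == oid), None)
        if partner_first is not None:
            src = organisms[org_ids.index(partner_first)]
            organisms.append(Organism(oid, src.genus, src.species, "B"))
        else:
            strain = "A" if any(a == oid for a, _ in pairs) else "1"
            organisms.append(Organism(oid, f"Genus{i + 1:02d}", f"species{i + 1:02d}", strain))

    G = config.genes_per_organism
    n_sc = int(round(config.fraction_single_copy * G))
    if n_sc > G:
        raise ValueError("single-copy families exceed the per-organism gene budget")
    n_sh = int(round(config.fraction_shared_families * (G - n_sc)))
    n_ex = G - n_sc - n_sh

    # --- family layout over base organisms ---------------------------------
    # each family: (member base-organism ids)
    families: list[list[str]] = [list(base_orgs) for _ in range(n_sc)]
    sc_flags = [True] * n_sc
    if n_sh > 0 and len(base_orgs) >= 2:
        quota = {o: n_sh for o in base_orgs}
        while True:
            open_orgs = [o for o in base_orgs if quota[o] > 0]
            if len(open_orgs) < 2:
                # a lone leftover quota becomes exclusive genes instead
                for o in open_orgs:
                    n_extra = quota[o]
                    quota[o] = 0
                    for _ in range(n_extra):
                        families.append([o])
                        sc_flags.append(False)
                break
            size = int(rng_layout.integers(2, min(3, len(open_orgs)) + 1))
            # favor the organisms with the most remaining quota, random ties
            order = rng_layout.permutation(len(open_orgs))
            open_orgs = [open_orgs[i] for i in order]
            open_orgs.sort(key=lambda o: -quota[o])
            members = sorted(open_orgs[:size])
            families.append(members)
            sc_flags.append(False)
            for o in members:
                quota[o] -= 1
    elif n_sh > 0:
        for _ in range(n_sh):
            families.append([base_orgs[0]])
            sc_flags.append(False)
    for o in base_orgs:
        for _ in range(n_ex):
            families.append([o])
            sc_flags.append(False)

    # --- strain partners mirror their partner's families --------------------
    # mirrored exclusive families become two-member shared families; the
    # partner's remaining genes are fresh exclusive families.
    for first, second in pairs:
        excl_idx = [
            i
            for i, mem in enumerate(families)
            if mem == [first] and not sc_flags[i]
        ]
        n_mirror = int(round(config.strain_exclusive_mirror * len(excl_idx)))
        chosen = rng_layout.choice(len(excl_idx), size=n_mirror, replace=False)
        chosen_idx = {excl_idx[int(c)] for c in chosen}
        for i, mem in enumerate(families):
            if first in mem and (sc_flags[i] or len(mem) > 1 or i in chosen_idx):
                mem.append(second)
        for _ in range(len(excl_idx) - n_mirror):
            families.append([second])
            sc_flags.append(False)

    # --- realize sequences ---------------------------------------------------
    lo, hi = config.gene_length
    counters = {o: 0 for o in org_ids}
    transcripts: dict[str, list[SequenceRecord]] = {o: [] for o in org_ids}
    groups: dict[str, dict[str, list[str]]] = {}
    function_labels: dict[str, str] = {}
    for fi, members in enumerate(families):
        og = f"OG{fi:07d}"
        ancestor = _random_orf(rng_seq, lo, hi)
        per_org: dict[str, list[str]] = {}
        partner_source: dict[str, str] = {}
        for org in members:
            counters[org] += 1
            gid = f"{org}_g{counters[org]:04d}"
            if org in mirror_of and mirror_of[org] in members:
                src_seq = partner_source[mirror_of[org]]
                seq = _repair_frame(
                    mutate_sequence(src_seq, config.strain_pair_sub_rate, seed=rng_seq)
                )
            elif len(members) == 1:
                seq = ancestor
            else:
                seq = _repair_frame(
                    mutate_sequence(ancestor, config.within_family_sub_rate, seed=rng_seq)
                )
            partner_source[org] = seq
            transcripts[org].append(SequenceRecord(gid, seq, description=og))
            per_org.setdefault(org, []).append(gid)
        groups[og] = per_org
        function_labels[og] = f"K{fi + 1:05d}"

    table = OrthogroupTable(groups, org_ids)
    return ReferencePanel(organisms, transcripts, table, pairs, function_labels, config)


def emit_truth_tables(panel: ReferencePanel, out_dir) -> dict[str, Path]:
    """Write per-organism FASTAs and the truth tables (orthogroups TSV,
    taxonomy TSV, function-label TSV); returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for org in panel.organism_ids():
        p = out / f"{org}.fasta"
        write_sequences(panel.transcripts[org], p)
        paths[org] = p
    paths["orthogroups"] = out / "Orthogroups.tsv"
    write_orthogroups(panel.truth_orthogroups, paths["orthogroups"])
    paths["taxonomy"] = out / "taxonomy.tsv"
    with open(paths["taxonomy"], "w") as fh:
        fh.write("organism\tgenus\tspecies\tstrain\n")
        for o in panel.organisms:
            fh.write(f"{o.id}\t{o.genus}\t{o.species}\t{o.strain}\n")
    paths["functions"] = out / "functions.tsv"
    with open(paths["functions"], "w") as fh:
        fh.write("orthogroup\tfunction\n")
        for og in sorted(panel.function_labels):
            fh.write(f"{og}\t{panel.function_labels[og]}\n")
    paths["strain_pairs"] = out / "strain_pairs.tsv"
    with open(paths["strain_pairs"], "w") as fh:
        fh.write("organism_a\torganism_b\n")
        for a, b in panel.strain_pairs:
            fh.write(f"{a}\t{b}\n")
    return paths
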
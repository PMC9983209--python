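"""Community templates and ortholog-aware designer-metatranscriptome assembly.

Six community templates span the complexity axes a mock eukaryotic
community can vary along: (1) dominance by a single organism, (2) a strain
pair making up the majority, (3) skew toward members rich in exclusive
genes, (4) high richness with multiple related pairs, (5) a community of
mutually related organisms, (6) maximal richness, evenly proportioned.
Template proportions are package defaults (the source descriptions are
qualitative) and all are overridable.

Contig selection realizes the ortholog-aware sampling rules: 10% of the
community's single-copy orthogroups are drawn at random and every member's
gene from each drawn group is force-included; each organism's remaining
quota (its share of the contig budget, largest-remainder rounded) is then
filled 75% from shared orthogroups / 25% from exclusive ones if the
organism has a highly related partner in the community, and 75% exclusive
/ 25% shared if it does not. Forced single-copy genes do not count against
quotas. Every selected contig gets a manifest row recording its source
organism, gene, orthogroup, selection category and expression weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .orthology import OrthogroupTable, single_copy_groups
from .panels import ReferencePanel
from .sequences import SequenceRecord
from .similarity import (
    CommunityProportions,
    composite_score,
    richness,
    shannon_index,
    similarity_matrix,
    sketch,
)

TEMPLATE_RICHNESS = {1: 4, 2: 5, 3: 8, 4: 10, 5: 7, 6: 12}


@dataclass
class CommunitySpec:
    """A community recipe: members, proportions, partner pairs, budget."""

    template_id: int
    members: list[str]
    proportions: CommunityProportions
    partner_pairs: list[tuple[str, str]] = field(default_factory=list)
    budget: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.template_id not in range(1, 7):
            raise ValueError("template id must be in 1..6")
        if list(self.proportions.ids) != list(self.members):
            raise ValueError("proportion ids must equal members")
        for a, b in self.partner_pairs:
            if a not in self.members or b not in self.members:
                raise ValueError(f"partner pair ({a}, {b}) outside community")

    def partnered(self, org: str) -> bool:
        return any(org in pair for pair in self.partner_pairs)


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` by ``fractions`` (sum 1), largest
    remainder, ties to the lower index."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    left = total - base.sum()
    if left > 0:
        rem = raw - base
        order = np.lexsort((np.arange(len(rem)), -rem))
        base[order[:left]] += 1
    return base


def make_template(
    template_id: int,
    members: Sequence[str],
    seed: int = 0,
    strain_pairs: Sequence[tuple[str, str]] = (),
    budget: int = 5000,
) -> CommunitySpec:
    """Instantiate one of the six templates over the available members.

    ``strain_pairs`` are the designated highly related pairs among
    ``members`` (from partner detection or panel truth); templates 2, 4 and
    5 place them preferentially. Member choice and ordering are
    deterministic per seed. Raises if too few members (or no strain pair
    where the template needs one).
    """
    r = TEMPLATE_RICHNESS[template_id]
    members = list(members)
    if len(members) < r:
        raise ValueError(f"template {template_id} needs {r} members, got {len(members)}")
    rng = np.random.default_rng(seed)
    pairs_avail = [p for p in strain_pairs if p[0] in members and p[1] in members]

    def pick_rest(chosen: list[str], n: int) -> list[str]:
        pool = [m for m in members if m not in chosen]
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[int(i)] for i in sorted(idx)]

    used_pairs: list[tuple[str, str]] = []
    if template_id == 2:
        if not pairs_avail:
            raise ValueError("template 2 requires a designated strain pair")
        a, b = pairs_avail[0]
        used_pairs = [(a, b)]
        chosen = [a, b] + pick_rest([a, b], r - 2)
        props = np.array([0.40, 0.35] + [0.25 / (r - 2)] * (r - 2))
    elif template_id in (4, 5):
        want = 2 if template_id == 4 else 1
        chosen = []
        for p in pairs_avail[:want]:
            chosen.extend(p)
            used_pairs.append(p)
        chosen += pick_rest(chosen, r - len(chosen))
        props = np.full(r, 1.0 / r)
    elif template_id == 1:
        chosen = pick_rest([], r)
        props = np.array([0.85] + [0.15 / (r - 1)] * (r - 1))
    elif template_id == 3:
        chosen = pick_rest([], r)
        props = 0.7 ** np.arange(r)
        props = props / props.sum()
    else:  # template 6: maximal richness, even
        chosen = pick_rest([], r)
        props = np.full(r, 1.0 / r)
    for p in pairs_avail:
        if p not in used_pairs and p[0] in chosen and p[1] in chosen:
            used_pairs.append(p)
    props = props / props.sum()
    return CommunitySpec(
        template_id,
        chosen,
        CommunityProportions(chosen, props),
        used_pairs,
        budget=budget,
        seed=seed,
    )


def select_contigs(
    spec: CommunitySpec,
    panel: ReferencePanel,
    orthogroups: OrthogroupTable,
    seed: int = 0,
    single_copy_fraction: float = 0.10,
    majority_fraction: float = 0.75,
    lognormal_weights: bool = False,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Select designer contigs for a community; returns (records, manifest).

    The manifest has one row per contig with columns contig_id, organism,
    gene_id, orthogroup, category (single_copy_forced / shared_og /
    exclusive_og) and weight. Weights are organism proportion / organism
    contig count (optionally with a lognormal(sigma=1) multiplier).
    Deterministic per seed; raises when a category pool cannot fill an
    organism's quota, naming the organism and shortfall.
    """
    rng = np.random.default_rng(seed)
    roster = spec.members
    missing = set(roster) - set(panel.transcripts)
    if missing:
        raise ValueError(f"community members absent from panel: {sorted(missing)}")
    gene_to_group = orthogroups.gene_to_group()

    # 1) forced single-copy orthogroups (10%, rounded)
    sc = sorted(single_copy_groups(orthogroups, roster))
    n_forced = int(round(single_copy_fraction * len(sc)))
    forced_groups = sorted(
        sc[int(i)] for i in rng.choice(len(sc), size=n_forced, replace=False)
    ) if sc else []
    rows = []
    selected: set[str] = set()
    for og in forced_groups:
        for org in roster:
            for gid in orthogroups.groups[og][org]:
                rows.append((gid, org, gid, og, "single_copy_forced"))
                selected.add(gid)

    # 2) per-organism quotas over the remaining budget
    remaining = spec.budget - len(rows)
    if remaining < 0:
        raise ValueError(
            f"budget {spec.budget} below forced single-copy count {len(rows)}"
        )
    quotas = _largest_remainder(remaining, spec.proportions.proportions)

    # community-restricted shared/exclusive pools per organism
    for org, quota in zip(roster, quotas):
        shared_pool, excl_pool = [], []
        for rec in panel.transcripts[org]:
            if rec.id in selected:
                continue
            og = gene_to_group.get(rec.id)
            if og is None:
                continue
            others = [
                o for o in roster
                if o != org and orthogroups.groups[og].get(o)
            ]
            (shared_pool if others else excl_pool).append(rec.id)
        shared_pool.sort()
        excl_pool.sort()
        if spec.partnered(org):
            want = {"shared_og": None, "exclusive_og": None}
            n_major = _largest_remainder(
                int(quota), np.array([majority_fraction, 1 - majority_fraction])
            )
            want["shared_og"], want["exclusive_og"] = int(n_major[0]), int(n_major[1])
        else:
            n_major = _largest_remainder(
                int(quota), np.array([majority_fraction, 1 - majority_fraction])
            )
            want = {"exclusive_og": int(n_major[0]), "shared_og": int(n_major[1])}
        for category, pool in (("shared_og", shared_pool), ("exclusive_og", excl_pool)):
            n = want[category]
            if n > len(pool):
                raise ValueError(
                    f"organism {org}: {category} pool exhausted "
                    f"(need {n}, have {len(pool)})"
                )
            picks = sorted(pool[int(i)] for i in rng.choice(len(pool), size=n, replace=False)) if n else []
            for gid in picks:
                rows.append((gid, org, gid, gene_to_group[gid], category))
                selected.add(gid)

    manifest = pd.DataFrame(
        rows, columns=["contig_id", "organism", "gene_id", "orthogroup", "category"]
    )
    if manifest["contig_id"].duplicated().any():
        raise AssertionError("duplicate contig selected")  # guarded by `selected`

    # 3) expression weights
    prop = dict(zip(roster, spec.proportions.proportions))
    counts = manifest["organism"].value_counts()
    weight = manifest["organism"].map(lambda o: prop[o] / counts[o]).to_numpy()
    if lognormal_weights:
        weight = weight * rng.lognormal(mean=0.0, sigma=1.0, size=len(weight))
    manifest["weight"] = weight

    records = [panel.record(gid) for gid in manifest["contig_id"]]
    return records, manifest


def designer_diversity(
    spec: CommunitySpec,
    panel: ReferencePanel,
    k: int = 31,
    sketch_size: int = 1000,
    hash_seed: int = 42,
) -> dict:
    """Shannon index, richness and composite score for a community spec,
    computed from member proportions and member-transcriptome sketches."""
    p = spec.proportions
    sketches = [
        sketch(panel.transcripts[org], k=k, sketch_size=sketch_size,
               hash_seed=hash_seed, source_id=org)
        for org in spec.members
    ]
    mat = similarity_matrix(sketches, kind="jaccard")
    return {
        "shannon": shannon_index(p),
        "richness": richness(p),
        "composite_score": composite_score(mat, p),
    }
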
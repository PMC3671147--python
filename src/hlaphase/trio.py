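"""Mendelian validation of phased calls in parent-child families.

A gene call is consistent when the child's two alleles can be
partitioned as one from the father's pair and one from the mother's
pair (multiset logic, homozygosity handled).  Across the six genes in
their chromosomal order (A-C-B-DRB1-DQB1-DPB1), each transmitted allele
is attributed to one of the parent's two multi-gene haplotypes; a
switch of parental-haplotype label between adjacent genes is one
recombination event.  The reported count is the minimum-switch
labeling, resolved jointly for both parents over all per-gene
transmission choices (a parent homozygous at a gene never breaks a run).

Allele identity is plain string equality: use allele names or sequence
digests, whichever is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FamilyGenotypes", "GENE_ORDER", "check_gene_transmission",
           "detect_recombination", "simulate_family"]

GENE_ORDER = ("HLA-A", "HLA-C", "HLA-B", "HLA-DRB1", "HLA-DQB1", "HLA-DPB1")

Pair = tuple[str, str]


@dataclass
class FamilyGenotypes:
    """Per-individual, per-gene allele pairs for one family.

    ``members`` maps role ('father', 'mother', 'child_1', ...) to a dict
    gene -> (allele, allele).  Parent pairs are ordered: index 0/1 are
    that parent's own haplotype 1/2.
    """

    family_id: str
    members: dict[str, dict[str, Pair]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role, genes in self.members.items():
            for gene, pair in genes.items():
                if len(pair) != 2:
                    raise ValueError(f"{role}/{gene}: need exactly two alleles")

    @property
    def children(self) -> list[str]:
        return sorted(r for r in self.members if r.startswith("child"))

    def require(self, role: str) -> dict[str, Pair]:
        if role not in self.members:
            raise ValueError(f"family {self.family_id}: missing individual {role!r}")
        return self.members[role]


def check_gene_transmission(child: Pair, father: Pair, mother: Pair) -> bool:
    """True iff the child pair splits into one paternal and one maternal
    allele (order-free; homozygous parents/children handled)."""
    c1, c2 = child
    return ((c1 in father and c2 in mother)
            or (c2 in father and c1 in mother))


def _gene_options(child: Pair, father: Pair, mother: Pair):
    """All (father haplotype labels, mother haplotype labels) consistent
    with this gene's transmission; labels are sets within {0, 1}."""
    options = []
    for cf, cm in ((child[0], child[1]), (child[1], child[0])):
        if cf in father and cm in mother:
            flab = frozenset(i for i in (0, 1) if father[i] == cf)
            mlab = frozenset(i for i in (0, 1) if mother[i] == cm)
            options.append((flab, mlab))
    # deduplicate (homozygous children yield the same option twice)
    return list(dict.fromkeys(options))


def _min_switch_labels(option_sets: list[list[frozenset]]) -> tuple[int, list[int]]:
    """Minimum number of label switches across genes, DP over the choice
    of haplotype label at each gene (labels constrained per gene)."""
    INF = 10 ** 9
    cost = {0: 0, 1: 0}
    back: list[dict[int, int]] = []
    for gi, allowed in enumerate(option_sets):
        ncost = {}
        nback = {}
        for lab in (0, 1):
            if lab not in allowed:
                ncost[lab] = INF
                nback[lab] = lab
                continue
            stay = cost[lab]
            switch = cost[1 - lab] + (1 if gi > 0 else 0)
            if stay <= switch:
                ncost[lab], nback[lab] = stay, lab
            else:
                ncost[lab], nback[lab] = switch, 1 - lab
        cost = ncost
        back.append(nback)
    lab = min((0, 1), key=lambda l: (cost[l], l))
    best = cost[lab]
    path = [lab]
    for nback in reversed(back[1:]):
        lab = nback[lab]
        path.append(lab)
    path.reverse()
    return best, path


def detect_recombination(family: FamilyGenotypes,
                         gene_order: tuple[str, ...] = GENE_ORDER) -> dict:
    """Per child: parental haplotype labels per gene and recombination
    events (junctions where the minimum-switch labeling switches).

    Raises when any gene is Mendelian-inconsistent — run
    :func:`check_gene_transmission` first to locate it.
    """
    father = family.require("father")
    mother = family.require("mother")
    report: dict[str, dict] = {}
    for child_role in family.children:
        child = family.require(child_role)
        genes = [g for g in gene_order if g in child]
        options: list[list[tuple[frozenset, frozenset]]] = []
        for g in genes:
            opts = _gene_options(child[g], father[g], mother[g])
            if not opts:
                raise ValueError(
                    f"{family.family_id}/{child_role}/{g}: inconsistent transmission; "
                    "check_gene_transmission")
            options.append(opts)
        # resolve jointly: enumerate per-gene transmission choices when
        # ambiguous, minimizing total switches father + mother
        best = None
        for combo in itertools.product(*options):
            fcost, fpath = _min_switch_labels([fl for fl, _ in combo])
            mcost, mpath = _min_switch_labels([ml for _, ml in combo])
            if best is None or fcost + mcost < best[0]:
                best = (fcost + mcost, fpath, mpath)
        assert best is not None
        total, fpath, mpath = best
        events = []
        for i in range(1, len(genes)):
            if fpath[i] != fpath[i - 1]:
                events.append(("father", genes[i - 1], genes[i]))
            if mpath[i] != mpath[i - 1]:
                events.append(("mother", genes[i - 1], genes[i]))
        report[child_role] = {
            "genes": genes,
            "father_haplotype": [p + 1 for p in fpath],
            "mother_haplotype": [p + 1 for p in mpath],
            "n_recombination": total,
            "events": events,
        }
    return report


def simulate_family(allele_pool: dict[str, list[str]],
                    rng: np.random.Generator,
                    n_children: int = 1,
                    father_pattern: list[int] | None = None,
                    mother_pattern: list[int] | None = None,
                    family_id: str = "fam") -> FamilyGenotypes:
    """Build a family by explicit transmission from random parent pairs.

    ``allele_pool`` maps gene -> candidate allele names.  Patterns give
    the parental haplotype index (0/1) transmitted at each gene; default
    is no recombination (haplotype 0 throughout).
    """
    genes = list(allele_pool)
    father = {g: tuple(rng.choice(allele_pool[g], size=2, replace=False))
              for g in genes}
    mother = {g: tuple(rng.choice(allele_pool[g], size=2, replace=False))
              for g in genes}
    members = {"father": father, "mother": mother}
    for c in range(1, n_children + 1):
        fp = father_pattern or [0] * len(genes)
        mp = mother_pattern or [0] * len(genes)
        child = {g: (father[g][fp[i]], mother[g][mp[i]])
                 for i, g in enumerate(genes)}
        members[f"child_{c}"] = child
    return FamilyGenotypes(family_id, members)
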
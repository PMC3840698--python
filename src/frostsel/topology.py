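"""The reference grass species topology and clade bookkeeping.

The study system is eight grass species: two PACMAD outgroups adapted to warm
climates (sorghum, maize), rice (Ehrhartoideae), and five temperate Pooideae
species — Brachypodium distachyon plus the core Pooideae crops wheat and
barley (Hordeeae) and Lolium perenne and Festuca pratensis (Poeae).

Two internal branches of this tree are the "foreground" branches on which the
branch-site test allows positive selection:

* ``BP_ancestral`` — the stem of Pooideae, after the split from rice but
  before the divergence of Brachypodium (the basal-Pooideae ancestral branch);
* ``CP_stem`` — the stem of the core Pooideae clade
  {wheat, barley, Lolium, Festuca}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

SORGHUM = "sorghum"
MAIZE = "maize"
RICE = "rice"
BRACHYPODIUM = "brachypodium"
WHEAT = "wheat"
BARLEY = "barley"
LOLIUM = "lolium"
FESTUCA = "festuca"

SPECIES: tuple[str, ...] = (
    SORGHUM, MAIZE, RICE, BRACHYPODIUM, WHEAT, BARLEY, LOLIUM, FESTUCA,
)
OUTGROUPS: tuple[str, str] = (SORGHUM, MAIZE)
HORDEEAE: tuple[str, str] = (WHEAT, BARLEY)
POEAE: tuple[str, str] = (LOLIUM, FESTUCA)
CORE_POOIDEAE: tuple[str, ...] = HORDEEAE + POEAE
POOIDEAE: tuple[str, ...] = (BRACHYPODIUM,) + CORE_POOIDEAE
#: orthology searches are anchored on the B. distachyon gene of each set
ANCHOR_SPECIES = BRACHYPODIUM

DEFAULT_NEWICK = (
    "((sorghum,maize),(rice,(brachypodium,"
    "((wheat,barley),(lolium,festuca)))));"
)

#: named branches, each identified by the leaf set of the clade it subtends
BRANCH_CLADES: dict[str, frozenset[str]] = {
    "pacmad": frozenset(OUTGROUPS),
    "bep": frozenset((RICE,) + POOIDEAE),
    "BP_ancestral": frozenset(POOIDEAE),
    "CP_stem": frozenset(CORE_POOIDEAE),
    "hordeeae": frozenset(HORDEEAE),
    "poeae": frozenset(POEAE),
    **{sp: frozenset({sp}) for sp in SPECIES},
}

FOREGROUND_BRANCHES: tuple[str, str] = ("BP_ancestral", "CP_stem")


@dataclass(frozen=True)
class SpeciesTopology:
    """Rooted reference topology with clade assignments.

    ``clade_map`` assigns each species to one of the groups used throughout
    the analysis: ``outgroup``, ``rice``, ``Bd``, ``Hordeeae``, ``Poeae``.
    """

    newick_string: str = DEFAULT_NEWICK
    taxa: tuple[str, ...] = SPECIES
    clade_map: dict[str, str] = field(default_factory=lambda: {
        SORGHUM: "outgroup", MAIZE: "outgroup", RICE: "rice",
        BRACHYPODIUM: "Bd", WHEAT: "Hordeeae", BARLEY: "Hordeeae",
        LOLIUM: "Poeae", FESTUCA: "Poeae",
    })
    foreground_branches: tuple[str, ...] = FOREGROUND_BRANCHES

    def __post_init__(self) -> None:
        missing = set(self.taxa) - set(self.clade_map)
        if missing:
            raise ValueError(f"taxa without clade assignment: {sorted(missing)}")
        for br in self.foreground_branches:
            clade = BRANCH_CLADES.get(br, frozenset())
            if not (1 < len(clade) < len(self.taxa)):
                raise ValueError(f"foreground branch {br!r} is not internal")

    def tree(self) -> dendropy.Tree:
        """A fresh rooted dendropy tree of the reference topology."""
        return dendropy.Tree.get(
            data=self.newick_string, schema="newick", rooting="force-rooted"
        )

    def pruned_tree(self, taxa: set[str] | frozenset[str]) -> dendropy.Tree:
        """Reference topology restricted to ``taxa`` (unifurcations removed)."""
        tree = self.tree()
        keep = [t for t in tree.taxon_namespace if t.label in taxa]
        tree.retain_taxa(keep)
        return tree

    def branch_clade(self, name: str) -> frozenset[str]:
        return BRANCH_CLADES[name]


def edge_for_clade(tree: dendropy.Tree, clade: frozenset[str]):
    """The edge of ``tree`` whose bipartition separates ``clade`` (restricted
    to the tree's taxa) from the rest, or None if no such edge exists.

    On an unrooted tree the branch is identified up to orientation, so an
    edge subtending the complement of the clade counts as the same branch.
    """
    present = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    target = clade & present
    if not target or target == present:
        return None
    complement = present - target
    fallback = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = {leaf.taxon.label for leaf in node.leaf_iter()}
        if leaves == target:
            return node.edge
        if leaves == complement and fallback is None:
            fallback = node.edge
    return fallback
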
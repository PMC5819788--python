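"""Parsimony mapping of karyotype characters on the genus phylogeny.

The packaged species tree transcribes the accepted infrageneric
classification of *Phalaris*: the two x = 6 species of subgenus
*Phalaris* (section *Phalaris*) are sister to the x = 7 subgenus
*Phalaroides*, within which *P. coerulescens* (section *Heterachne*)
subtends section *Bulbophalaris* (*P. paradoxa* and the two B/C
allotetraploids), and *P. caroliniana* (section *Caroliniana*) groups
with *P. arundinacea* (section *Phalaroides*).  Branch lengths are
omitted; only the topology is asserted.

Characters (basic number, ploidy, genome formula) are mapped by
unordered (Fitch) small parsimony: the minimum number of state changes
plus per-node candidate state sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Any, Hashable

import dendropy

from .genomes import assign
from .model import Karyotype

Tree = dendropy.Tree

#: Section assignment of the studied species (subgenus/section scheme).
SECTIONS = {
    "P. brachystachys": "Phalaris",
    "P. canariensis": "Phalaris",
    "P. aquatica": "Bulbophalaris",
    "P. minor": "Bulbophalaris",
    "P. paradoxa": "Bulbophalaris",
    "P. caroliniana": "Caroliniana",
    "P. coerulescens": "Heterachne",
    "P. arundinacea": "Phalaroides",
}


class NewickError(ValueError):
    pass


def read_newick(text: str) -> Tree:
    """Parse a newick string (underscores in unquoted labels read as
    spaces, the usual convention).  Malformed input raises NewickError
    carrying the parser's line/column diagnostics."""
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(str(exc)) from exc


def write_newick(tree: Tree) -> str:
    """Serialize topology, labels and any branch lengths; spaces in
    labels are written as underscores, so write -> read is stable."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"


def load_species_tree() -> Tree:
    """The packaged 8-species topology."""
    text = (
        resources.files("karyokit").joinpath("data/trees/phalaris.nwk").read_text()
    )
    return read_newick(text)


def leaf_names(tree: Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def fitch(
    tree: Tree, character: dict[str, Hashable]
) -> tuple[int, dict[int, frozenset]]:
    """Fitch small parsimony for one unordered character.

    Returns the minimum number of state changes on the tree and the
    candidate state set of every node, keyed by a stable node index
    (postorder position).  Polytomies are folded child by child.
    """
    leaves = [l for l in tree.leaf_node_iter() if l.taxon is not None]
    if tree.seed_node is None or not leaves:
        raise ValueError("empty tree")
    missing = [l.taxon.label for l in leaves if l.taxon.label not in character]
    if missing:
        raise ValueError(f"no state for leaves: {', '.join(sorted(missing))}")
    changes = 0
    sets: dict[int, frozenset] = {}
    for i, node in enumerate(tree.postorder_node_iter()):
        node._fitch_index = i
        if node.is_leaf():
            sets[i] = frozenset([character[node.taxon.label]])
            continue
        children = node.child_nodes()
        acc = sets[children[0]._fitch_index]
        for child in children[1:]:
            nxt = sets[child._fitch_index]
            if acc & nxt:
                acc = acc & nxt
            else:
                acc = acc | nxt
                changes += 1
        sets[i] = acc
    return changes, sets


def _clade_leaves(node) -> tuple[str, ...]:
    return tuple(sorted(l.taxon.label for l in node.leaf_iter()))


def change_edges(tree: Tree, character: dict[str, Hashable]) -> list[dict[str, Any]]:
    """Edges on which one most-parsimonious reconstruction places the
    changes.  Node states are resolved top-down: keep the parent state
    when the node's candidate set allows it, otherwise the smallest
    candidate (deterministic tie-break).  Each change is reported with
    the leaf set below the edge and the parent/child states."""
    _, sets = fitch(tree, character)
    out = []
    for node in tree.preorder_node_iter():
        candidates = sets[node._fitch_index]
        if node.parent_node is None:
            node._fitch_state = min(candidates, key=repr)
            continue
        parent_state = node.parent_node._fitch_state
        if parent_state in candidates:
            node._fitch_state = parent_state
        else:
            node._fitch_state = min(candidates, key=repr)
            out.append(
                {
                    "clade": _clade_leaves(node),
                    "from": parent_state,
                    "to": node._fitch_state,
                }
            )
    return out


@dataclass(frozen=True)
class CharacterReport:
    character: str
    states: dict[str, Hashable]
    min_changes: int
    changes: tuple[dict[str, Any], ...]


def character_matrix(karyotypes: dict[str, Karyotype]) -> dict[str, dict[str, Hashable]]:
    """Discrete characters per species, derived from the karyotypes:
    basic number, ploidy and the assigned genome formula."""
    chars: dict[str, dict[str, Hashable]] = {
        "basic_number": {},
        "ploidy": {},
        "genome_formula": {},
    }
    for name, k in karyotypes.items():
        chars["basic_number"][name] = k.basic_number_x
        chars["ploidy"][name] = k.ploidy
        chars["genome_formula"][name] = assign(k).formula
    return chars


def map_characters(tree: Tree, karyotypes: dict[str, Karyotype]) -> dict[str, Any]:
    """Fitch-map the karyotype characters and test the genome-restriction
    statements (genome A confined to section *Phalaris*, genome C to
    section *Bulbophalaris*, genome B present in every x = 7 species)."""
    leaves = leaf_names(tree)
    missing = [l for l in leaves if l not in karyotypes]
    if missing:
        raise ValueError(f"no karyotype for leaves: {', '.join(sorted(missing))}")
    subset = {name: karyotypes[name] for name in leaves}
    chars = character_matrix(subset)
    reports = {}
    for name, states in chars.items():
        n_changes, _ = fitch(tree, states)
        reports[name] = CharacterReport(
            character=name,
            states=states,
            min_changes=n_changes,
            changes=tuple(change_edges(tree, states)),
        )
    formulas = chars["genome_formula"]
    a_species = {s for s, f in formulas.items() if "A" in f}
    c_species = {s for s, f in formulas.items() if "C" in f}
    x7_species = {s for s, k in subset.items() if k.basic_number_x == 7}
    checks = {
        "genome_A_confined_to_section_Phalaris": all(
            SECTIONS.get(s) == "Phalaris" for s in a_species
        )
        and bool(a_species),
        "genome_C_confined_to_section_Bulbophalaris": all(
            SECTIONS.get(s) == "Bulbophalaris" for s in c_species
        )
        and bool(c_species),
        "genome_B_in_all_x7_species": all("B" in formulas[s] for s in x7_species),
    }
    return {"characters": reports, "checks": checks}
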
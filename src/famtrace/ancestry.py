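"""Points of origin, secondary losses and duplication placement.

Two classic parsimony tools applied to the survey's output:

* **Dollo origin inference** — a gene family is assumed to be gained
  exactly once (no lateral transfer) and lost arbitrarily often.  The
  gain maps to the last common ancestor of all species where the family
  is present; the losses are the maximal presence-free subtrees strictly
  below the gain.  This single-gain scenario provably minimises the loss
  count: placing the gain above the LCA can only add loss subtrees, and
  below it would leave presence leaves unexplained.  A gain at the root
  is labelled ``Ancient`` (present in the last common ancestor of the
  sampled species); otherwise the origin is named after the most specific
  labelled clade at or above the gain node.

* **LCA reconciliation** — each gene-tree node maps to the LCA of its
  descendants' species; a node whose child maps to the same species-tree
  node is a duplication, placed on the species-tree branch above the
  mapped node.

Species with no proteome (``missing`` cells) are treated as unobserved:
they contribute neither presence nor loss evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from .trees import SpeciesTree

PRESENT_STATES = ("+", "p")


@dataclass
class OriginAssignment:
    """One family's inferred gain node, loss subtrees and origin label."""

    family: str
    gain: str | None                 # species-tree node id; None = no origin
    losses: tuple[str, ...]          # ids of maximal presence-free subtrees
    n_losses: int
    label: str                       # "Ancient" | clade label | "no origin"
    flagged: bool = False            # label came from an ancestor, not the gain

    def loss_leaf_sets(self, tree: SpeciesTree) -> list[frozenset[str]]:
        return [tree.leaves_under(n) for n in self.losses]


def _normalise_pattern(pattern) -> dict[str, str]:
    """Accept {'sp': '+'/'p'/'-'/'.'} or {'sp': 'present'/...} patterns."""
    alias = {
        "+": "present",
        "p": "present",
        "-": "absent",
        ".": "missing",
        "present": "present",
        "absent": "absent",
        "missing": "missing",
        True: "present",
        False: "absent",
    }
    out = {}
    for sp, v in pattern.items():
        if v not in alias:
            raise ValueError(f"unknown presence state {v!r} for species {sp!r}")
        out[sp] = alias[v]
    return out


def dollo_origin(
    pattern, tree: SpeciesTree, family: str = "family"
) -> OriginAssignment:
    """Single-gain (Dollo) origin and minimal loss set for one family.

    ``pattern`` maps each species to a presence state; species absent
    from the mapping and species marked missing are unobserved.  An
    all-absent pattern yields a "no origin" assignment rather than an
    error.
    """
    states = _normalise_pattern(pattern)
    unknown = set(states) - set(tree.species)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    present = [sp for sp, v in states.items() if v == "present"]
    if not present:
        return OriginAssignment(family, None, (), 0, "no origin")
    gain = tree.mrca(present)
    present_set = set(present)
    observed_absent = {sp for sp, v in states.items() if v == "absent"}

    losses: list[str] = []

    def walk(node: str) -> None:
        leaves = tree.leaves_under(node)
        if leaves & present_set:
            for c in tree.children(node):
                walk(c)
            return
        # presence-free subtree: a loss only if it contains observed absence;
        # an all-missing subtree is uninformative
        if leaves & observed_absent:
            losses.append(node)

    for c in tree.children(gain):
        walk(c)
    label, flagged = label_origin_node(gain, tree)
    order = {nid: i for i, nid in enumerate(tree.preorder_ids())}
    losses.sort(key=lambda n: order[n])
    return OriginAssignment(family, gain, tuple(losses), len(losses), label, flagged)


def label_origin_node(gain: str, tree: SpeciesTree) -> tuple[str, bool]:
    """Name a gain node: root -> 'Ancient', else most specific clade label.

    When the gain node itself is unlabeled the nearest labelled ancestor
    provides the name and the assignment is flagged; with no labelled
    ancestor at all the origin falls back to 'Ancient' (flagged).
    """
    if gain == tree.root_id:
        return "Ancient", False
    lbl = tree.label_of(gain)
    if lbl:
        return lbl, False
    if tree.is_leaf(gain):
        return gain, False
    anc = tree.nearest_labeled_ancestor(gain)
    if anc is None or anc == tree.root_id:
        return "Ancient", True
    return tree.label_of(anc), True


def label_origin(assignment: OriginAssignment, tree: SpeciesTree) -> str:
    if assignment.gain is None:
        return "no origin"
    return label_origin_node(assignment.gain, tree)[0]


# ------------------------------------------------------------ reconciliation
@dataclass
class ReconciliationResult:
    """LCA mapping of a gene tree into a species tree."""

    node_map: dict[int, str]        # gene-node index (postorder) -> species node
    events: dict[int, str]          # internal gene-node index -> event
    duplication_branches: tuple[str, ...]  # species-tree edges (node-below ids)

    @property
    def n_duplications(self) -> int:
        return len(self.duplication_branches)


def default_leaf_species(leaf_label: str) -> str:
    """Gene ids of the form '<species>_<family>_g<k>' map by prefix."""
    return leaf_label.split("_")[0]


def lca_reconcile(
    gene_tree: "str | dendropy.Tree",
    species_tree: SpeciesTree,
    leaf_species=None,
) -> ReconciliationResult:
    """Standard LCA gene-tree/species-tree reconciliation.

    ``gene_tree`` is a rooted Newick string (or dendropy tree);
    ``leaf_species`` maps gene-tree leaf labels to species ids (default:
    the prefix convention of the simulator).  A duplication is a gene
    node with a child mapping to the same species node; it is assigned
    to the species-tree branch above that node.
    """
    if isinstance(gene_tree, str):
        gtree = dendropy.Tree.get(
            data=gene_tree, schema="newick", preserve_underscores=True
        )
    else:
        gtree = gene_tree
    gtree.is_rooted = True
    if leaf_species is None:
        leaf_species = default_leaf_species
    if not callable(leaf_species):
        mapping = dict(leaf_species)
        leaf_species = mapping.__getitem__

    node_map: dict[int, str] = {}
    events: dict[int, str] = {}
    dup_branches: list[str] = []
    idx: dict[int, int] = {}
    for i, node in enumerate(gtree.postorder_node_iter()):
        idx[id(node)] = i
        if node.is_leaf():
            if node.taxon is None:
                raise ValueError("gene-tree leaf without a label")
            sp = leaf_species(node.taxon.label)
            if not species_tree.has_node(sp) or not species_tree.is_leaf(sp):
                raise ValueError(
                    f"gene-tree leaf {node.taxon.label!r} maps to unknown species {sp!r}"
                )
            node_map[i] = sp
        else:
            child_maps = [node_map[idx[id(c)]] for c in node.child_nodes()]
            m = species_tree.mrca(child_maps)
            node_map[i] = m
            if any(cm == m for cm in child_maps):
                events[i] = "duplication"
                dup_branches.append(m)
            else:
                events[i] = "speciation"
    return ReconciliationResult(node_map, events, tuple(sorted(dup_branches)))


# ------------------------------------------------------------------- report
def origins_report(
    matrix, tree: SpeciesTree, paralog_as_presence: bool = True
) -> pd.DataFrame:
    """Per-family origin table from a presence matrix.

    Columns: family, gain_node, label, flagged, n_losses, loss_clades
    (semicolon-joined node ids of the maximal loss subtrees).
    """
    positive = PRESENT_STATES if paralog_as_presence else ("+",)
    rows = []
    for fam in matrix.families:
        pattern = {}
        for sp in matrix.species:
            cell = matrix.cell(fam, sp)
            pattern[sp] = "present" if cell in positive else (
                "missing" if cell == "." else "absent"
            )
        a = dollo_origin(pattern, tree, family=fam)
        rows.append(
            {
                "family": fam,
                "gain_node": a.gain if a.gain is not None else "",
                "label": a.label,
                "flagged": a.flagged,
                "n_losses": a.n_losses,
                "loss_clades": ";".join(a.losses),
            }
        )
    return pd.DataFrame(rows)
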
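"""Rooted, annotated species trees.

A :class:`SpeciesTree` wraps a rooted binary :class:`dendropy.Tree` and adds
the bookkeeping the rest of the pipeline needs: stable node identifiers,
a species -> lineage taxonomy map (the colour groups used when aggregating a
presence matrix), last-common-ancestor queries, patristic distances between
species, and clade labels on internal nodes (e.g. ``Metazoa``) used to name
points of origin.

Node identifiers are stable and deterministic: a leaf is identified by its
taxon label, an internal node by its Newick label when present, otherwise by
``N<k>`` where ``k`` is the node's preorder index.  An edge is identified by
the id of the node below it.
"""

from __future__ import annotations

import random
from pathlib import Path

import dendropy


class TreeError(ValueError):
    """Raised for structurally invalid trees (unrooted, duplicate labels...)."""


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column (species, lineage) TSV into a dict.

    Lines starting with ``#`` and a ``species<TAB>lineage`` header line are
    ignored.
    """
    taxonomy: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise TreeError(f"malformed taxonomy line: {line!r}")
        if parts[0] == "species" and parts[1] == "lineage":
            continue
        taxonomy[parts[0]] = parts[1]
    return taxonomy


def write_taxonomy(taxonomy: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tlineage\n")
        for sp, lin in taxonomy.items():
            fh.write(f"{sp}\t{lin}\n")


class SpeciesTree:
    """A rooted binary species tree with taxonomy and clade labels.

    Parameters
    ----------
    tree:
        A rooted dendropy tree.  Every internal node must have exactly two
        children (a trifurcating root is the classic signature of an
        unrooted tree and is rejected).
    taxonomy:
        Optional species -> lineage map.  When omitted every species is
        assigned the lineage ``"all"``.
    """

    def __init__(self, tree: dendropy.Tree, taxonomy: dict[str, str] | None = None):
        self._tree = tree
        self._id2node: dict[str, dendropy.Node] = {}
        self._parent: dict[str, str | None] = {}
        self._children: dict[str, tuple[str, ...]] = {}
        self._depth: dict[str, float] = {}
        self._leafset: dict[str, frozenset[str]] = {}
        self._preorder: list[str] = []

        root = tree.seed_node
        if root is None:
            raise TreeError("empty tree")
        # Assign ids in preorder; validate binary structure.
        for k, node in enumerate(tree.preorder_node_iter()):
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise TreeError("leaf without a taxon label")
                nid = node.taxon.label
            else:
                nchild = len(node.child_nodes())
                if nchild != 2:
                    where = "root" if node is root else "internal node"
                    raise TreeError(
                        f"{where} with {nchild} children; a rooted binary tree is "
                        "required (a trifurcating root indicates an unrooted tree)"
                    )
                nid = node.label if node.label else f"N{k}"
            if nid in self._id2node:
                raise TreeError(f"duplicate node id {nid!r}")
            node.famtrace_id = nid
            self._id2node[nid] = node
            self._preorder.append(nid)

        for nid, node in self._id2node.items():
            par = node.parent_node
            self._parent[nid] = par.famtrace_id if par is not None else None
            self._children[nid] = tuple(c.famtrace_id for c in node.child_nodes())
            elen = node.edge.length if node.edge.length is not None else 0.0
            if elen < 0:
                raise TreeError(f"negative branch length above {nid!r}")
            if par is None:
                self._depth[nid] = 0.0
        for nid in self._preorder[1:]:
            node = self._id2node[nid]
            elen = node.edge.length if node.edge.length is not None else 0.0
            self._depth[nid] = self._depth[self._parent[nid]] + elen
        for nid in reversed(self._preorder):
            if self.is_leaf(nid):
                self._leafset[nid] = frozenset([nid])
            else:
                s: frozenset[str] = frozenset()
                for c in self._children[nid]:
                    s |= self._leafset[c]
                self._leafset[nid] = s

        self.root_id: str = root.famtrace_id
        self.species: tuple[str, ...] = tuple(
            nid for nid in self._preorder if self.is_leaf(nid)
        )
        if taxonomy is None:
            taxonomy = {sp: "all" for sp in self.species}
        missing = set(self.species) - set(taxonomy)
        if missing:
            raise TreeError(f"species missing from taxonomy: {sorted(missing)}")
        self.taxonomy: dict[str, str] = {sp: taxonomy[sp] for sp in self.species}
        self.lineages: tuple[str, ...] = tuple(dict.fromkeys(self.taxonomy.values()))

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(
        cls, source: str | Path, taxonomy: dict[str, str] | None = None
    ) -> "SpeciesTree":
        """Load from a Newick file path or a literal Newick string."""
        src = str(source)
        try:
            if src.lstrip().startswith("("):
                tree = dendropy.Tree.get(
                    data=src, schema="newick", preserve_underscores=True
                )
            else:
                tree = dendropy.Tree.get(
                    path=src, schema="newick", preserve_underscores=True
                )
        except dendropy.utility.error.DataParseError as exc:
            raise TreeError(f"invalid Newick input: {exc}") from exc
        tree.is_rooted = True
        return cls(tree, taxonomy)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # ------------------------------------------------------------- structure
    def is_leaf(self, node_id: str) -> bool:
        return not self._children[node_id]

    def parent(self, node_id: str) -> str | None:
        return self._parent[node_id]

    def children(self, node_id: str) -> tuple[str, ...]:
        return self._children[node_id]

    def branch_length(self, node_id: str) -> float:
        """Length of the edge above ``node_id`` (0 for the root)."""
        node = self._id2node[node_id]
        return node.edge.length if node.edge.length is not None else 0.0

    def set_clade_label(self, node_id: str, label: str) -> None:
        """Attach a clade label to an internal node (e.g. from a labels TSV)."""
        if self.is_leaf(node_id):
            raise TreeError("clade labels belong on internal nodes")
        self._id2node[node_id].label = label

    def label_of(self, node_id: str) -> str | None:
        """Explicit clade label of an internal node, if any."""
        node = self._id2node[node_id]
        if node.is_leaf():
            return None
        return node.label or None

    def preorder_ids(self) -> list[str]:
        return list(self._preorder)

    def postorder_ids(self) -> list[str]:
        return list(reversed(self._preorder))

    def leaves_under(self, node_id: str) -> frozenset[str]:
        return self._leafset[node_id]

    def depth(self, node_id: str) -> float:
        """Sum of branch lengths from the root down to ``node_id``."""
        return self._depth[node_id]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._id2node

    # ------------------------------------------------------------- ancestry
    def ancestors(self, node_id: str) -> list[str]:
        """Ancestors of a node, nearest first, excluding the node itself."""
        out = []
        cur = self._parent[node_id]
        while cur is not None:
            out.append(cur)
            cur = self._parent[cur]
        return out

    def mrca(self, node_ids) -> str:
        """Most recent common ancestor of a non-empty collection of node ids."""
        ids = list(node_ids)
        if not ids:
            raise TreeError("mrca of an empty set")
        cur = ids[0]
        rest = [self._leafset[i] for i in ids[1:]]
        while True:
            cover = self._leafset[cur]
            if all(r <= cover for r in rest) and all(
                self._is_ancestor_or_self(cur, i) for i in ids
            ):
                return cur
            par = self._parent[cur]
            if par is None:
                return cur
            cur = par

    def _is_ancestor_or_self(self, anc: str, node: str) -> bool:
        cur: str | None = node
        while cur is not None:
            if cur == anc:
                return True
            cur = self._parent[cur]
        return False

    def nearest_labeled_ancestor(self, node_id: str) -> str | None:
        """Closest node at/above ``node_id`` carrying a clade label."""
        cur: str | None = node_id
        while cur is not None:
            if self.label_of(cur):
                return cur
            cur = self._parent[cur]
        return None

    def path_distance(self, a: str, b: str) -> float:
        """Patristic distance (sum of branch lengths) between two nodes."""
        lca = self.mrca([a, b])
        return self._depth[a] + self._depth[b] - 2.0 * self._depth[lca]


def random_species_tree(
    n_species: int,
    seed: int,
    mean_root_to_tip: float = 0.6,
    n_lineages: int = 5,
    species_prefix: str = "S",
) -> SpeciesTree:
    """Simulate a random rooted binary species tree with ``n_species`` leaves.

    A pure-birth (Yule) tree is drawn with dendropy, branch lengths are
    rescaled so the mean root-to-tip path length equals ``mean_root_to_tip``
    (expected substitutions per site), species are renamed
    ``<prefix>01..<prefix>NN`` in leaf order, and leaves are partitioned into
    ``n_lineages`` monophyletic lineage groups of roughly balanced size.
    """
    if n_species < 2:
        raise TreeError("need at least 2 species")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace(
        [f"{species_prefix}{i + 1:02d}" for i in range(n_species)]
    )
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        taxon_namespace=taxa,
        rng=rng,
    )
    tree.is_rooted = True
    # dendropy may leave a zero/None root edge; normalise.
    tree.seed_node.edge.length = None
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    mean_depth = sum(depths) / len(depths)
    if mean_depth > 0:
        scale = mean_root_to_tip / mean_depth
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    st = SpeciesTree(tree, taxonomy={t.label: "all" for t in taxa})
    st.taxonomy = assign_lineages(st, n_lineages)
    st.lineages = tuple(dict.fromkeys(st.taxonomy.values()))
    return st


def assign_lineages(tree: SpeciesTree, n_lineages: int) -> dict[str, str]:
    """Partition the species into ``n_lineages`` monophyletic groups.

    Starting from the root clade, the largest current group is repeatedly
    split into its two child clades until the requested number of groups is
    reached; groups are then labelled ``L1..Lk`` in tree (preorder) order.
    Deterministic for a given tree.
    """
    n_lineages = min(n_lineages, len(tree.species))
    groups = [tree.root_id]
    while len(groups) < n_lineages:
        groups.sort(key=lambda nid: (-len(tree.leaves_under(nid)), nid))
        big = groups[0]
        if tree.is_leaf(big):
            break
        groups = list(tree.children(big)) + groups[1:]
    order = {nid: i for i, nid in enumerate(tree.preorder_ids())}
    groups.sort(key=lambda nid: order[nid])
    taxonomy: dict[str, str] = {}
    for i, g in enumerate(groups, start=1):
        for sp in sorted(tree.leaves_under(g)):
            taxonomy[sp] = f"L{i}"
    return taxonomy
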
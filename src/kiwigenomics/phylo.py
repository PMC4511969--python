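"""Phylogenies with foreground-branch tags.

Trees are read from Newick; branches may carry CODEML-style ``#1`` tags
marking them as foreground for two-ratio branch models ("the focal species
is the foreground branch, the other birds background"). Internally the
tree is flattened to parent/child index arrays so the pruning likelihood
and the simulator can run vectorized.

Branch lengths are expected substitutions per codon. A bifurcating root is
collapsed (the model is time-reversible, so root placement is arbitrary);
a two-taxon tree is re-rooted at its first leaf with the total path length
on the single remaining edge.
"""

from __future__ import annotations

import re

import dendropy

_FG_RE = re.compile(r"\s*#\s*(\d+)")
_FG_SENTINEL = "@@FG{}@@"


class PhyloTree:
    """Rooted-representation phylogeny over index-addressed nodes.

    Node 0..n_leaves-1 are leaves (in ``taxa`` order); the root is the last
    node. ``parent[i]`` is -1 for the root; ``lengths[i]`` and
    ``foreground[i]`` describe the edge above node i.
    """

    def __init__(self, taxa, parent, lengths, foreground, names=None):
        self.taxa = list(taxa)
        self.parent = list(parent)
        self.lengths = [float(x) for x in lengths]
        self.foreground = list(foreground)
        self.n_nodes = len(self.parent)
        self.n_leaves = len(self.taxa)
        self.names = list(names) if names else self.taxa + [""] * (self.n_nodes - self.n_leaves)
        self.root = self.parent.index(-1)
        self.children = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self._validate()

    def _validate(self):
        if self.parent.count(-1) != 1:
            raise ValueError("tree must have exactly one root")
        for i, t in enumerate(self.lengths):
            if i != self.root and t < 0:
                raise ValueError(f"negative branch length on edge above node {i}")
        for i in range(self.n_leaves):
            # a two-taxon tree is rooted at a leaf; otherwise leaves are tips
            if self.children[i] and i != self.root:
                raise ValueError(f"leaf node {i} has children")

    @property
    def n_foreground(self) -> int:
        return sum(1 for i, f in enumerate(self.foreground) if f and i != self.root)

    def postorder(self):
        """Node indices, children always before parents, root last."""
        order, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return order

    def edges(self):
        """Non-root node indices (each identifies the edge above it)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def with_foreground_taxon(self, taxon: str) -> "PhyloTree":
        """Copy with only the terminal branch of ``taxon`` tagged foreground."""
        if taxon not in self.taxa:
            raise ValueError(f"unknown taxon {taxon!r}")
        fg = [False] * self.n_nodes
        fg[self.taxa.index(taxon)] = True
        return PhyloTree(self.taxa, self.parent, self.lengths, fg, self.names)

    def with_lengths(self, lengths) -> "PhyloTree":
        out = PhyloTree(self.taxa, self.parent, list(lengths), self.foreground, self.names)
        return out

    # ------------------------------------------------------------------ IO

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse Newick; ``#N`` after a leaf/clade marks its edge foreground.

        Tags are accepted both before the branch length (``kiwi #1:0.1``,
        the CODEML placement) and after it (``kiwi:0.1 #1``).
        """
        # move tags that trail a branch length back onto the label
        newick = re.sub(
            r":\s*([0-9eE.+\-]+)\s*#\s*(\d+)", lambda m: f"@@FG{m.group(2)}@@:{m.group(1)}",
            newick,
        )
        marked = _FG_RE.sub(lambda m: _FG_SENTINEL.format(m.group(1)), newick)
        tree = dendropy.Tree.get(
            data=marked, schema="newick", suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
        return cls._from_dendropy(tree)

    @classmethod
    def _from_dendropy(cls, tree: "dendropy.Tree") -> "PhyloTree":
        def strip_fg(label):
            if label is None:
                return None, False
            m = re.search(r"@@FG(\d+)@@", label)
            if m:
                return label[: m.start()].strip() or None, True
            return label, False

        root = tree.seed_node
        # collapse a bifurcating root (unrooted-tree convention)
        if len(root.child_nodes()) == 2:
            a, b = root.child_nodes()
            internal = a if a.child_nodes() else b
            other = b if internal is a else a
            if internal.child_nodes():
                el = (internal.edge.length or 0.0) + (other.edge.length or 0.0)
                root.remove_child(internal)
                for ch in list(internal.child_nodes()):
                    internal.remove_child(ch)
                    root.add_child(ch)
                other.edge.length = el
                # a tag on either merged half marks the merged edge
                lab_i, fg_i = strip_fg(
                    internal.taxon.label if internal.taxon else internal.label
                )
                lab_o, fg_o = strip_fg(other.taxon.label if other.taxon else other.label)
                if fg_i and not fg_o:
                    base = other.taxon.label if other.taxon else (other.label or "")
                    newlab = (lab_o or base or "") + _FG_SENTINEL.format(1)
                    if other.taxon:
                        other.taxon.label = newlab
                    else:
                        other.label = newlab

        leaves, internals = [], []
        for nd in tree.postorder_node_iter():
            (leaves if nd.is_leaf() else internals).append(nd)
        nodes = leaves + internals  # root (last internal in postorder) ends up last
        idx = {id(nd): i for i, nd in enumerate(nodes)}

        taxa, parent, lengths, fg, names = [], [0] * len(nodes), [0.0] * len(nodes), [
            False
        ] * len(nodes), [""] * len(nodes)
        for nd in nodes:
            i = idx[id(nd)]
            raw = nd.taxon.label if nd.taxon else nd.label
            label, tagged = strip_fg(raw)
            names[i] = label or ""
            fg[i] = tagged
            if nd.parent_node is None:
                parent[i] = -1
            else:
                parent[i] = idx[id(nd.parent_node)]
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
        taxa = [names[i] for i in range(len(leaves))]
        if any(not t for t in taxa):
            raise ValueError("every leaf must be named")
        tr = cls(taxa, parent, lengths, fg, names)
        if tr.n_leaves == 2 and tr.root == tr.n_nodes - 1 and tr.n_nodes == 3:
            # two-taxon tree: only the path length is identifiable
            total = tr.lengths[0] + tr.lengths[1]
            anyfg = tr.foreground[0] or tr.foreground[1]
            return cls(tr.taxa, [-1, 0], [0.0, total], [False, anyfg], tr.taxa)
        return tr

    def to_newick(self) -> str:
        def fmt(i):
            tag = " #1" if self.foreground[i] and i != self.root else ""
            if not self.children[i]:
                return f"{self.names[i]}{tag}:{self.lengths[i]:.6f}"
            inner = ",".join(fmt(c) for c in self.children[i])
            if i == self.root:
                return f"({inner});"
            return f"({inner}){tag}:{self.lengths[i]:.6f}"

        return fmt(self.root)

    def __repr__(self):
        return (
            f"PhyloTree(n_leaves={self.n_leaves}, n_nodes={self.n_nodes}, "
            f"foreground_edges={self.n_foreground})"
        )
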
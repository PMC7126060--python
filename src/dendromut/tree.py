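"""Physical (ontogenetic) tree of a sampled plant.

The plant's branching structure is treated as a rooted phylogeny whose root is
the ground/germline genotype, whose internal nodes are physical branching
points, and whose leaves are the sampled branch tips.  Edge lengths are metres
of physical growth.  Each leaf carries one or more biological replicates that
were sequenced independently but share the leaf's underlying genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


class TreeError(ValueError):
    pass


@dataclass
class PhysicalTree:
    """Rooted tree with metre branch lengths and replicate groupings.

    Edges are keyed by their child node: ``length[c]`` is the length of the
    edge from ``parent[c]`` to ``c``.  The root has ``parent[root] is None``
    and no edge above it.
    """

    root: str
    parent: dict[str, str | None]
    children: dict[str, list[str]]
    length: dict[str, float]
    replicate_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicate_map:
            # default: 3 replicates per leaf, named <leaf>.1 .. <leaf>.3
            self.replicate_map = {
                lf: [f"{lf}.{i}" for i in (1, 2, 3)] for lf in self.leaves
            }
        self.validate()

    # -- structure -------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.parent if not self.children.get(n)]

    @property
    def edges(self) -> list[tuple[str, str]]:
        """(parent, child) pairs, child-keyed, in postorder."""
        return [(self.parent[n], n) for n in self.postorder() if self.parent[n] is not None]

    def postorder(self) -> list[str]:
        out: list[str] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for c in self.children.get(node, []):
                    stack.append((c, False))
        return out

    def descendant_leaves(self, node: str) -> list[str]:
        """Leaves in the subtree rooted at ``node`` (the clade below the edge
        parent(node)→node)."""
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            kids = self.children.get(n, [])
            if not kids:
                out.append(n)
            stack.extend(kids)
        return out

    # -- lengths ---------------------------------------------------------

    def total_length(self) -> float:
        return sum(self.length[c] for _, c in self.edges)

    def leaf_path_lengths(self) -> dict[str, float]:
        depth = {self.root: 0.0}
        for node in reversed(self.postorder()):  # preorder
            for c in self.children.get(node, []):
                depth[c] = depth[node] + self.length[c]
        return {lf: depth[lf] for lf in self.leaves}

    # -- replicates ------------------------------------------------------

    @property
    def replicates(self) -> list[str]:
        """All replicate sample ids, grouped by leaf, in leaf order."""
        return [r for lf in self.leaves for r in self.replicate_map[lf]]

    def leaf_of_replicate(self) -> dict[str, str]:
        return {r: lf for lf, reps in self.replicate_map.items() for r in reps}

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.parent.get(self.root, "missing") is not None:
            raise TreeError("root must have parent None")
        for c, p in self.parent.items():
            if p is not None and c not in self.children.get(p, []):
                raise TreeError(f"inconsistent parent/children at {c}")
            if p is not None and self.length.get(c, -1.0) < 0:
                raise TreeError(f"edge above {c} missing or negative length")
        for lf in self.leaves:
            if not self.replicate_map.get(lf):
                raise TreeError(f"leaf {lf} has no replicates")
        reps = self.replicates
        if len(set(reps)) != len(reps):
            raise TreeError("replicate ids must be unique")

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, replicate_map: dict[str, list[str]] | None = None) -> "PhysicalTree":
        dt = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=False)
        parent: dict[str, str | None] = {}
        children: dict[str, list[str]] = {}
        length: dict[str, float] = {}
        counter = [0]

        def name_of(nd) -> str:
            if nd.taxon is not None and nd.taxon.label:
                return nd.taxon.label
            if nd.label:
                return nd.label
            counter[0] += 1
            nd.label = f"_n{counter[0]}"
            return nd.label

        root = name_of(dt.seed_node)
        parent[root] = None
        for nd in dt.preorder_node_iter():
            nm = name_of(nd)
            children.setdefault(nm, [])
            for ch in nd.child_nodes():
                cn = name_of(ch)
                parent[cn] = nm
                children[nm].append(cn)
                length[cn] = float(ch.edge.length or 0.0)
        return cls(root=root, parent=parent, children=children, length=length,
                   replicate_map=replicate_map or {})

    def to_newick(self) -> str:
        def rec(node: str) -> str:
            kids = self.children.get(node, [])
            if not kids:
                return f"{node}:{self.length.get(node, 0.0):g}"
            inner = ",".join(rec(c) for c in kids)
            if node == self.root:
                return f"({inner}){node}"
            return f"({inner}){node}:{self.length[node]:g}"

        return rec(self.root) + ";"

    def as_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 suppress_internal_node_taxa=False)

    def replicate_topology(self) -> tuple[list[str], list[tuple[int, int]]]:
        """Binary topology over replicate tips.

        Each leaf with k replicates is expanded into a caterpillar of its
        replicate tips, so a fully binary physical tree yields a fully binary
        replicate-level tree (24 tips for 8 leaves x 3 replicates).  Returns
        (tip labels, edge list over integer node ids; tips are 0..n_tips-1).
        """
        tips = self.replicates
        tip_id = {t: i for i, t in enumerate(tips)}
        next_id = [len(tips)]
        edges: list[tuple[int, int]] = []

        def fresh() -> int:
            next_id[0] += 1
            return next_id[0] - 1

        def expand_leaf(leaf: str) -> int:
            reps = self.replicate_map[leaf]
            node = tip_id[reps[0]]
            for r in reps[1:]:
                joint = fresh()
                edges.append((joint, node))
                edges.append((joint, tip_id[r]))
                node = joint
            return node

        def rec(node: str) -> int:
            kids = self.children.get(node, [])
            if not kids:
                return expand_leaf(node)
            ids = [rec(c) for c in kids]
            cur = ids[0]
            for other in ids[1:]:
                joint = fresh()
                edges.append((joint, cur))
                edges.append((joint, other))
                cur = joint
            return cur

        rec(self.root)
        return tips, edges
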
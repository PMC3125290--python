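"""Rooted haplotype trees with per-branch mutation lists.

The phylogeny is an input (PhyloTree-/Mitomap-style topologies or the
simulator), never inferred here. Branches carry explicit substitution
events; tip-to-ancestor distances are event counts along root paths under a
mutation-class filter (synonymous only, all coding, or an HVS1 position
window). This module also scores "ancestral sequences" (AS): extant
haplotypes identical to an internal ancestor, whose phylogenetic lifespan
Da/(Da+Db) compares the divergence of their relatives (Da) with the depth of
the ancestor below the super-lineage MRCA (Db).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .genetic_code import (
    CODING_CLASSES,
    CodingAnnotation,
    MutationClass,
    Substitution,
    classify_substitution,
)

logger = logging.getLogger("mitoclock")

#: inclusive HVS1 analysis window (rCRS coordinates)
HVS1_WINDOW = (16090, 16383)


@dataclass
class BranchEvent:
    """One substitution on a branch, optionally pre-classified."""

    substitution: Substitution
    mutation_class: MutationClass | None = None


@dataclass
class Node:
    node_id: str
    parent: "Node | None" = None
    children: list["Node"] = field(default_factory=list)
    #: events on the branch leading to this node (empty at the root)
    events: list[BranchEvent] = field(default_factory=list)
    #: branch length (e.g. generations or expected substitutions); optional
    length: float | None = None
    label: str | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children


class ClassFilter:
    """Predicate over branch events: which events count toward a distance."""

    def __init__(self, name: str, fn: Callable[[BranchEvent], bool]):
        self.name = name
        self._fn = fn

    def __call__(self, event: BranchEvent) -> bool:
        return self._fn(event)


def _cls(event: BranchEvent) -> MutationClass | None:
    return event.mutation_class


SYNONYMOUS_FILTER = ClassFilter(
    "synonymous", lambda e: _cls(e) is MutationClass.SYNONYMOUS
)
CODING_FILTER = ClassFilter("all_coding", lambda e: _cls(e) in CODING_CLASSES)
HVS1_FILTER = ClassFilter(
    "hvs1",
    lambda e: HVS1_WINDOW[0] <= e.substitution.position <= HVS1_WINDOW[1],
)
ALL_FILTER = ClassFilter("all", lambda e: True)

FILTERS: dict[str, ClassFilter] = {
    f.name: f for f in (SYNONYMOUS_FILTER, CODING_FILTER, HVS1_FILTER, ALL_FILTER)
}


class HaplotypeTree:
    """Rooted clade tree; tips are observed haplotypes, named internal nodes
    define clades (MRCA-R, MRCA-R0, ...)."""

    def __init__(self, root: Node):
        self.root = root
        self.nodes: dict[str, Node] = {}
        self.clades: dict[str, str] = {}
        for node in self.preorder():
            if node.node_id in self.nodes:
                raise ValueError(f"duplicate node id {node.node_id!r}")
            self.nodes[node.node_id] = node
            if node.label:
                self.clades[node.label] = node.node_id

    # ------------------------------------------------------------ traversal
    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def node(self, node_id: str) -> Node:
        return self.nodes[node_id]

    def clade_node(self, label: str) -> Node:
        return self.nodes[self.clades[label]]

    def set_label(self, node_id: str, label: str) -> None:
        self.nodes[node_id].label = label
        self.clades[label] = node_id

    def tips_below(self, node: Node) -> list[Node]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n)
            stack.extend(n.children)
        return out

    def path_to_ancestor(self, node: Node, ancestor: Node) -> list[Node]:
        """Nodes whose branches lie on the node->ancestor path (node first).

        Raises ValueError when ``ancestor`` is not on the node's root path.
        """
        path = []
        cur = node
        while cur is not ancestor:
            if cur.parent is None:
                raise ValueError(
                    f"{ancestor.node_id!r} is not an ancestor of {node.node_id!r}"
                )
            path.append(cur)
            cur = cur.parent
        return path

    def is_descendant(self, node: Node, ancestor: Node) -> bool:
        cur = node
        while cur is not None:
            if cur is ancestor:
                return True
            cur = cur.parent
        return False

    def path_count(self, node: Node, ancestor: Node, class_filter: ClassFilter) -> int:
        return sum(
            1
            for n in self.path_to_ancestor(node, ancestor)
            for e in n.events
            if class_filter(e)
        )

    # ----------------------------------------------------------- classify
    def classify_events(self, annotation: CodingAnnotation, reference: str) -> None:
        """Assign a MutationClass to every branch event, using the root
        reference for codon context (mutations are rare enough on these
        trees that the reference context is the ancestral context in almost
        all cases; pre-classified events are left untouched)."""
        for node in self.preorder():
            for ev in node.events:
                if ev.mutation_class is not None:
                    continue
                ctx = annotation.codon_context(ev.substitution.position, reference)
                if ctx is None:
                    ev.mutation_class = classify_substitution(
                        ev.substitution, None, annotation
                    )
                else:
                    codon, off = ctx
                    ev.mutation_class = classify_substitution(
                        ev.substitution, codon, annotation, offset=off
                    )

    # ------------------------------------------------------------------ IO
    def to_branch_frame(self) -> pd.DataFrame:
        rows = []
        for node in self.preorder():
            if node.parent is None:
                continue
            subs = ";".join(str(e.substitution) for e in node.events)
            cls = ";".join(
                e.mutation_class.value if e.mutation_class else "" for e in node.events
            )
            rows.append(
                {
                    "child": node.node_id,
                    "parent": node.parent.node_id,
                    "substitutions": subs,
                    "classes": cls,
                    "label": node.label or "",
                    "length": node.length if node.length is not None else "",
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_branch_frame().to_csv(path, sep="\t", index=False)

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            name = node.node_id
            length = (
                f":{node.length:.6g}" if node.length is not None else ""
            )
            if node.is_tip:
                return f"{name}{length}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){name}{length}"

        return f"[&R] {fmt(self.root)};"


def build_tree(
    branch_table: pd.DataFrame | Sequence[tuple],
    clade_labels: Mapping[str, str] | None = None,
) -> HaplotypeTree:
    """Build a :class:`HaplotypeTree` from a (child, parent, substitutions)
    table.

    ``branch_table`` may be a DataFrame with columns ``child``, ``parent``,
    ``substitutions`` (semicolon-separated ``A8701G`` tokens, may be empty)
    and optionally ``classes``, ``label``, ``length`` — or an iterable of
    (child, parent, substitutions) tuples. ``clade_labels`` maps labels to
    node ids and overrides any label column. Cycles, duplicate child rows
    and multiple roots are hard errors.
    """
    if not isinstance(branch_table, pd.DataFrame):
        branch_table = pd.DataFrame(
            branch_table, columns=["child", "parent", "substitutions"]
        )
    nodes: dict[str, Node] = {}

    def get(node_id: str) -> Node:
        if node_id not in nodes:
            nodes[node_id] = Node(node_id)
        return nodes[node_id]

    seen_children: set[str] = set()
    for row in branch_table.to_dict("records"):
        child_id, parent_id = str(row["child"]), str(row["parent"])
        if child_id in seen_children:
            raise ValueError(f"duplicate child row {child_id!r}")
        seen_children.add(child_id)
        child, parent = get(child_id), get(parent_id)
        if child.parent is not None:
            raise ValueError(f"node {child_id!r} has two parents")
        child.parent = parent
        parent.children.append(child)
        subs = row.get("substitutions", "")
        tokens = [t for t in str(subs or "").split(";") if t]
        classes = [c for c in str(row.get("classes", "") or "").split(";")]
        for i, tok in enumerate(tokens):
            mc = None
            if i < len(classes) and classes[i]:
                mc = MutationClass(classes[i])
            child.events.append(BranchEvent(Substitution.parse(tok), mc))
        label = row.get("label")
        if isinstance(label, str) and label:
            child.label = label
        length = row.get("length", "")
        if length not in ("", None) and not pd.isna(length):
            child.length = float(length)

    roots = [n for n in nodes.values() if n.parent is None]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root, found {len(roots)}")
    root = roots[0]
    # cycle check: every node must reach the root
    for node in nodes.values():
        cur, hops = node, 0
        while cur.parent is not None:
            cur = cur.parent
            hops += 1
            if hops > len(nodes):
                raise ValueError("cycle detected in branch table")
    if clade_labels:
        for label, node_id in clade_labels.items():
            nodes[node_id].label = label
    return HaplotypeTree(root)


def read_tree_tsv(path, clade_labels: Mapping[str, str] | None = None) -> HaplotypeTree:
    return build_tree(pd.read_csv(path, sep="\t", keep_default_na=False), clade_labels)


# --------------------------------------------------------------- distances
@dataclass
class DistanceProfile:
    """Per-tip derived-mutation counts relative to a designated ancestor."""

    counts: dict[str, int]
    class_filter: str
    ancestor: str

    @property
    def n(self) -> int:
        return len(self.counts)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.counts.values())))

    @property
    def sd(self) -> float:
        vals = list(self.counts.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")

    def restrict(self, tip_ids: Iterable[str]) -> "DistanceProfile":
        keep = set(tip_ids)
        return DistanceProfile(
            {t: c for t, c in self.counts.items() if t in keep},
            self.class_filter,
            self.ancestor,
        )

    def values(self) -> list[int]:
        return list(self.counts.values())


def distance_profile(
    tree: HaplotypeTree,
    ancestor: str | Node,
    class_filter: ClassFilter | str = SYNONYMOUS_FILTER,
    tips: Iterable[Node] | None = None,
) -> DistanceProfile:
    """Count branch substitutions matching the filter along each tip's path
    to ``ancestor``. Tips that are not descendants of the ancestor are
    excluded with a warning."""
    if isinstance(class_filter, str):
        class_filter = FILTERS[class_filter]
    anc = tree.node(ancestor) if isinstance(ancestor, str) else ancestor
    counts: dict[str, int] = {}
    for tip in tips if tips is not None else tree.tips:
        if not tree.is_descendant(tip, anc):
            logger.warning(
                "tip %s is not a descendant of %s; excluded", tip.node_id, anc.node_id
            )
            continue
        counts[tip.node_id] = tree.path_count(tip, anc, class_filter)
    return DistanceProfile(counts, class_filter.name, anc.node_id)


# -------------------------------------------------------- ancestral sequences
@dataclass
class AncestralSequenceRecord:
    """An internal ancestor still carried unchanged by extant haplotypes."""

    node_id: str
    carrier_tips: list[str]
    n_related: int
    da: float  #: mean distance AS -> diverged related present haplotypes
    da_sd: float
    db: float  #: distance AS -> super-lineage MRCA
    lifespan: float  #: Da/(Da+Db), in [0, 1]


def as_lifespan(da: float, db: float) -> float:
    """Phylogenetic lifespan ratio Da/(Da+Db).

    Da is the mean distance from the ancestral sequence to its diverged
    present relatives, Db its distance to the super-lineage MRCA. The
    orientation is the one that reproduces the published per-clade
    percentages (e.g. (Da=3.70, Db=6) -> 38.14%).
    """
    if da < 0 or db < 0:
        raise ValueError("distances must be non-negative")
    if da + db == 0:
        raise ValueError("lifespan undefined when Da + Db = 0")
    return da / (da + db)


def find_ancestral_sequences(
    tree: HaplotypeTree,
    super_mrca: str | Node | None = None,
    detect_filter: ClassFilter | str = CODING_FILTER,
    distance_filter: ClassFilter | str = SYNONYMOUS_FILTER,
    dedupe: bool = True,
) -> list[AncestralSequenceRecord]:
    """Find internal nodes whose sequence is still carried by >=1 extant tip.

    A node qualifies when at least one descendant tip has zero derived
    mutations below it under ``detect_filter`` (the carrier) and at least
    one descendant tip has diverged. Da/Db are measured under
    ``distance_filter``. When several nested nodes share the same carriers,
    only the highest (closest-to-root) node is kept — the oldest ancestral
    sequence. Records are sorted by lifespan, descending.
    """
    if isinstance(detect_filter, str):
        detect_filter = FILTERS[detect_filter]
    if isinstance(distance_filter, str):
        distance_filter = FILTERS[distance_filter]
    mrca = (
        tree.root
        if super_mrca is None
        else (tree.node(super_mrca) if isinstance(super_mrca, str) else super_mrca)
    )
    depth = {tree.root.node_id: 0}
    for node in tree.preorder():
        if node.parent is not None:
            depth[node.node_id] = depth[node.parent.node_id] + 1

    records: list[AncestralSequenceRecord] = []
    for node in tree.preorder():
        if node.is_tip:
            continue
        if not tree.is_descendant(node, mrca):
            continue
        tips = tree.tips_below(node)
        carriers = [t for t in tips if tree.path_count(t, node, detect_filter) == 0]
        related = [t for t in tips if tree.path_count(t, node, detect_filter) > 0]
        if not carriers or not related:
            continue
        dists = [tree.path_count(t, node, distance_filter) for t in related]
        da = float(np.mean(dists))
        da_sd = float(np.std(dists, ddof=1)) if len(dists) > 1 else float("nan")
        db = float(tree.path_count(node, mrca, distance_filter))
        records.append(
            AncestralSequenceRecord(
                node_id=node.node_id,
                carrier_tips=sorted(t.node_id for t in carriers),
                n_related=len(related),
                da=da,
                da_sd=da_sd,
                db=db,
                lifespan=as_lifespan(da, db) if da + db > 0 else 1.0,
            )
        )
    if dedupe:
        best: dict[frozenset, AncestralSequenceRecord] = {}
        for rec in records:
            key = frozenset(rec.carrier_tips)
            if key not in best or depth[rec.node_id] < depth[best[key].node_id]:
                best[key] = rec
        records = list(best.values())
    return sorted(records, key=lambda r: -r.lifespan)


def ancestral_sequence_table(records: list[AncestralSequenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        columns=["node", "carriers", "n_related", "db", "da", "da_sd", "lifespan_pct"],
        data=[
            {
                "node": r.node_id,
                "carriers": ",".join(r.carrier_tips),
                "n_related": r.n_related,
                "db": r.db,
                "da": round(r.da, 2),
                "da_sd": round(r.da_sd, 2),
                "lifespan_pct": round(100 * r.lifespan, 2),
            }
            for r in records
        ]
    )


def induced_subtree(tree: HaplotypeTree, tip_ids: Iterable[str]) -> HaplotypeTree:
    """Subtree induced by a tip subset.

    Keeps the sampled tips and every ancestor with >=2 sampled-descendant
    children; unary pass-through nodes are suppressed, concatenating their
    branch events and summing branch lengths onto the retained child. The
    root of the induced tree is the original root (its depth matters for
    rho-style distances), even if unary.
    """
    keep = set(tip_ids)
    missing = keep - {t.node_id for t in tree.tips}
    if missing:
        raise ValueError(f"unknown tips: {sorted(missing)[:5]}")

    def prune(node: Node) -> Node | None:
        if node.is_tip:
            if node.node_id not in keep:
                return None
            return Node(node.node_id, events=list(node.events), length=node.length,
                        label=node.label)
        kept_children = [c for c in (prune(ch) for ch in node.children) if c]
        if not kept_children:
            return None
        if len(kept_children) == 1 and node.parent is not None:
            # suppress unary node: fold this branch into the child
            child = kept_children[0]
            child.events = list(node.events) + child.events
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            return child
        new = Node(node.node_id, events=list(node.events), length=node.length,
                   label=node.label)
        for c in kept_children:
            c.parent = new
        new.children = kept_children
        return new

    root = prune(tree.root)
    if root is None:
        raise ValueError("no tips retained")
    root.parent = None
    return HaplotypeTree(root)


# --------------------------------------------------------- root-to-tip means
def root_to_tip_distances(
    trees: str | dendropy.Tree | Sequence,
    group_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group mean root-to-tip branch-length distance.

    ``trees`` is a rooted dendropy Tree, a Newick string, or a sequence of
    either (a posterior sample); every tip must be assigned to a group in
    ``group_map``. For a sample of trees the result rows average the
    per-tree group means (the posterior mean distance per group).
    Unrooted input is refused: rho-style depths need an explicit root.
    """
    if isinstance(trees, (str, dendropy.Tree)):
        trees = [trees]
    per_tree: list[dict[str, float]] = []
    for t in trees:
        if isinstance(t, str):
            t = dendropy.Tree.get(data=t, schema="newick")
        if not t.is_rooted:
            raise ValueError(
                "tree is unrooted; root it explicitly ('[&R]' in Newick)"
            )
        dists: dict[str, list[float]] = {}
        for leaf in t.leaf_node_iter():
            name = leaf.taxon.label if leaf.taxon else None
            if name is None or name not in group_map:
                raise ValueError(f"tip {name!r} has no group assignment")
            d = 0.0
            cur = leaf
            while cur.parent_node is not None:
                d += cur.edge.length or 0.0
                cur = cur.parent_node
            dists.setdefault(group_map[name], []).append(d)
        per_tree.append({g: float(np.mean(v)) for g, v in dists.items()})
    frame = pd.DataFrame(per_tree)
    out = pd.DataFrame(
        {
            "group": frame.columns,
            "mean_distance": frame.mean(axis=0).values,
            "n_trees": len(per_tree),
        }
    )
    return out
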
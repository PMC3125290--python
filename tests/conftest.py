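"""Shared fixtures: a toy coding annotation (heavy + light strand genes,
an rRNA span), a matching reference sequence, and small deterministic trees.
All fixtures are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from mitoclock import (
    BranchEvent,
    CodingAnnotation,
    GeneSpan,
    HaplotypeTree,
    MutationClass,
    Node,
    Substitution,
    build_tree,
)

# codons used to build the toy reference (no stops in either code)
_G1_CODONS = ["CTA", "GCC", "ATT", "ACA", "GGC", "TTA", "CGT", "ATA", "TCC", "AAC"]
_G2_CODONS = ["ATG", "CCA", "GTT", "AAA", "GGA", "TGC", "CTT"]  # read on light strand


@pytest.fixture(scope="session")
def toy_annotation() -> CodingAnnotation:
    """Heavy-strand gene G1 (1-30), rRNA span (31-36), light-strand gene
    G2 (37-57), noncoding tail (58-60)."""
    return CodingAnnotation(
        [
            GeneSpan("G1", 1, 30, strand="heavy"),
            GeneSpan("rrna", 31, 36, kind="rRNA"),
            GeneSpan("G2", 37, 57, strand="light"),
        ]
    )


@pytest.fixture(scope="session")
def toy_reference() -> str:
    g1 = "".join(_G1_CODONS)
    # light-strand gene: reading codons occupy reference positions end..start
    # descending, complemented
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    g2_read = "".join(_G2_CODONS)
    ref_bases = [""] * 21
    span_start = 37
    for i, base in enumerate(g2_read):
        pos = 57 - i  # reading order walks down the reference
        ref_bases[pos - span_start] = comp[base]
    return g1 + "AACCGG" + "".join(ref_bases) + "TTT"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_caterpillar(counts: list[int]) -> HaplotypeTree:
    """A comb tree: internal chain i0->i1->..., each internal node bearing
    one tip whose branch carries ``counts[k]`` synonymous events."""
    rows = []
    pos = 100
    parent = "root"
    for k, c in enumerate(counts):
        inner = f"i{k}"
        rows.append((inner, parent, ""))
        subs = ";".join(f"A{pos + 3 * j}G" for j in range(c))
        pos += 3 * c + 3
        rows.append((f"tip{k}", inner, subs))
        parent = inner
    tree = build_tree(rows)
    for node in tree.preorder():
        for ev in node.events:
            ev.mutation_class = MutationClass.SYNONYMOUS
    return tree


def star_clade(
    parent: Node, tip_counts: list[int], prefix: str, start_pos: int = 1000
) -> int:
    """Attach tips below ``parent``, each with the given number of
    synonymous events; returns the next free position."""
    pos = start_pos
    for i, c in enumerate(tip_counts):
        tip = Node(f"{prefix}{i}", parent=parent)
        parent.children.append(tip)
        for _ in range(c):
            tip.events.append(
                BranchEvent(Substitution(pos, "A", "G"), MutationClass.SYNONYMOUS)
            )
            pos += 1
    return pos
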
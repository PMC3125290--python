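"""Counting-based per-branch and per-lineage dN/dS.

Branch-class omega contrasts (stems of a focal haplogroup vs a slow lineage
vs the remaining branches) are computed by Nei–Gojobori-style counting:
ancestral sequences are reconstructed by Fitch parsimony, each branch's
codon differences are decomposed into single-base steps averaged over all
minimal substitution orders, and counts are normalised by the fractional
synonymous/non-synonymous site content of the ancestral sequence. Omega for
a class is (Nobs/Nsites)/(Sobs/Ssites); a class with zero observed
synonymous changes has undefined omega, reported with the ``"*"``
convention. This replaces maximum-likelihood codon-model fitting; the
meaningful surface is the ordering and zero/undefined structure of the
class omegas, not their absolute ML values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    BASES,
    CodingAnnotation,
    count_synonymous_sites,
    translate_codon,
)
from .haplotree import HaplotypeTree

logger = logging.getLogger("mitoclock")

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_BIT_BASE = {v: k for k, v in _BASE_BITS.items()}
_FIRST_BASE = np.zeros(16, dtype="<U1")
for _bit in (1, 2, 4, 8):  # lowest set bit -> base, A<C<G<T order
    for _mask in range(16):
        if _mask & _bit and not _FIRST_BASE[_mask]:
            _FIRST_BASE[_mask] = _BIT_BASE[_bit]


@dataclass
class BranchCounts:
    branch_id: str
    n_obs: float
    s_obs: float
    n_sites: float
    s_sites: float

    @property
    def omega(self) -> float | None:
        if self.s_obs == 0:
            return None
        if self.n_sites == 0 or self.s_sites == 0:
            return None
        return (self.n_obs / self.n_sites) / (self.s_obs / self.s_sites)


@dataclass
class OmegaReport:
    scope: str  #: branch | lineage-class | tree
    label: str
    n_obs: float
    s_obs: float
    dn: float  #: per-site non-synonymous divergence
    ds: float  #: per-site synonymous divergence
    omega: float | None  #: None = undefined (printed "*")

    @property
    def omega_str(self) -> str:
        return "*" if self.omega is None else f"{self.omega:.2f}"


_BIT_LOOKUP = np.zeros(256, dtype=np.uint8)
for _base, _b in _BASE_BITS.items():
    _BIT_LOOKUP[ord(_base)] = _b
    _BIT_LOOKUP[ord(_base.lower())] = _b


def _seq_to_bits(seq: str) -> np.ndarray:
    return _BIT_LOOKUP[np.frombuffer(seq.encode(), dtype=np.uint8)]


_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _codon_pair(
    parent_seq: str, child_seq: str, gene, ci: int
) -> tuple[str, str] | None:
    """Parent/child codons of one codon slot, in reading orientation
    (complemented base-by-base for light-strand genes; codon_positions
    already yields reading order). None when either codon is ambiguous."""
    coords = gene.codon_positions(ci)
    a = "".join(parent_seq[p - 1] for p in coords).upper()
    b = "".join(child_seq[p - 1] for p in coords).upper()
    if any(x not in BASES for x in a + b):
        return None
    if gene.strand == "light":
        a = "".join(_COMPLEMENT_BASE[x] for x in a)
        b = "".join(_COMPLEMENT_BASE[x] for x in b)
    return a, b


def reconstruct_ancestors(
    tree: HaplotypeTree, tip_sequences: Mapping[str, str]
) -> dict[str, str]:
    """Fitch parsimony ancestral reconstruction over every site.

    Up-pass: a node's state set is the intersection of its children's sets
    when non-empty, else the union. Down-pass: the root takes the
    alphabetically first base of its set; a child keeps the parent state
    when possible, otherwise its own first base (deterministic tie-break
    toward the root state). Returns node id -> sequence for all nodes,
    tips included.
    """
    tips = tree.tips
    missing = [t.node_id for t in tips if t.node_id not in tip_sequences]
    if missing:
        raise ValueError(f"tips without sequences: {missing[:5]}")
    lengths = {len(tip_sequences[t.node_id]) for t in tips}
    if len(lengths) != 1:
        raise ValueError("tip sequences must be aligned to equal length")
    (L,) = lengths

    sets: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            sets[node.node_id] = _seq_to_bits(tip_sequences[node.node_id])
        else:
            acc = sets[node.children[0].node_id]
            for child in node.children[1:]:
                inter = acc & sets[child.node_id]
                union = acc | sets[child.node_id]
                acc = np.where(inter != 0, inter, union)
            sets[node.node_id] = acc

    states: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        own = sets[node.node_id]
        if node.parent is None:
            states[node.node_id] = _FIRST_BASE[own]
        else:
            parent_state = states[node.parent.node_id]
            parent_bits = np.array(
                [_BASE_BITS.get(b, 0) for b in parent_state], dtype=np.uint8
            )
            keep = (own & parent_bits) != 0
            states[node.node_id] = np.where(keep, parent_state, _FIRST_BASE[own])
    return {nid: "".join(arr) for nid, arr in states.items()}


def _pathway_counts(
    codon_a: str, codon_b: str, code_id: int
) -> tuple[float, float]:
    """(nonsyn, syn) steps between two codons, averaged over all minimal
    substitution orders with uniform weights."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    n_tot = s_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diffs):
        cur = codon_a
        n = s = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if translate_codon(cur, code_id) == translate_codon(nxt, code_id):
                s += 1
            else:
                n += 1
            cur = nxt
        n_tot += n
        s_tot += s
        n_paths += 1
    return n_tot / n_paths, s_tot / n_paths


def branch_counts(
    parent_seq: str,
    child_seq: str,
    annotation: CodingAnnotation,
    branch_id: str = "",
) -> BranchCounts:
    """Nei–Gojobori counts for one branch.

    Each differing codon is decomposed into single-base steps averaged over
    all substitution orders; site counts come from the parent (ancestral)
    sequence. Codons containing ambiguous bases are skipped.
    """
    if len(parent_seq) != len(child_seq):
        raise ValueError("sequences must be equal length")
    sites = count_synonymous_sites(annotation, parent_seq)
    n_obs = s_obs = 0.0
    pa = np.frombuffer(parent_seq.upper().encode(), dtype="S1")
    ch = np.frombuffer(child_seq.upper().encode(), dtype="S1")
    diff_pos = np.nonzero(pa != ch)[0] + 1  # 1-based
    seen_codons: set[tuple[str, int]] = set()
    for pos in diff_pos:
        hit = annotation.locate(int(pos))
        if hit is None:
            continue
        gene, ci, _off = hit
        key = (gene.gene, ci)
        if key in seen_codons:
            continue
        seen_codons.add(key)
        pair = _codon_pair(parent_seq, child_seq, gene, ci)
        if pair is None:
            logger.debug("ambiguous codon skipped at %s[%d]", gene.gene, ci)
            continue
        n, s = _pathway_counts(*pair, annotation.code_id)
        n_obs += n
        s_obs += s
    return BranchCounts(branch_id, n_obs, s_obs, sites.nonsynonymous, sites.synonymous)


def tree_branch_counts(
    tree: HaplotypeTree,
    sequences: Mapping[str, str],
    annotation: CodingAnnotation,
) -> list[BranchCounts]:
    """Per-branch counts given node sequences (tips + reconstructed
    ancestors, e.g. from :func:`reconstruct_ancestors`). Site counts are
    computed once from the root sequence — at the divergences involved the
    per-branch fractional sites are indistinguishable and the single
    evaluation keeps large trees cheap."""
    sites = count_synonymous_sites(annotation, sequences[tree.root.node_id])
    out: list[BranchCounts] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_seq = sequences[node.parent.node_id]
        child_seq = sequences[node.node_id]
        n_obs = s_obs = 0.0
        pa = np.frombuffer(parent_seq.upper().encode(), dtype="S1")
        ch = np.frombuffer(child_seq.upper().encode(), dtype="S1")
        diff_pos = np.nonzero(pa != ch)[0] + 1
        seen: set[tuple[str, int]] = set()
        for pos in diff_pos:
            hit = annotation.locate(int(pos))
            if hit is None:
                continue
            gene, ci, _off = hit
            if (gene.gene, ci) in seen:
                continue
            seen.add((gene.gene, ci))
            pair = _codon_pair(parent_seq, child_seq, gene, ci)
            if pair is None:
                continue
            n, s = _pathway_counts(*pair, annotation.code_id)
            n_obs += n
            s_obs += s
        out.append(
            BranchCounts(
                node.node_id, n_obs, s_obs, sites.nonsynonymous, sites.synonymous
            )
        )
    return out


def _pool(counts: Sequence[BranchCounts], scope: str, label: str) -> OmegaReport:
    n_obs = sum(c.n_obs for c in counts)
    s_obs = sum(c.s_obs for c in counts)
    dn = sum(c.n_obs / c.n_sites for c in counts if c.n_sites > 0)
    ds = sum(c.s_obs / c.s_sites for c in counts if c.s_sites > 0)
    omega = (dn / ds) if ds > 0 else None
    return OmegaReport(scope, label, n_obs, s_obs, dn, ds, omega)


def lineage_omega(
    counts: Sequence[BranchCounts],
    branch_class_map: Mapping[str, str],
) -> list[OmegaReport]:
    """Pooled omega per branch class, plus the tree-wide pooled omega.

    Every branch must be assigned a class. dN and dS are summed per-branch
    per-site divergences; omega = dN/dS, undefined (``"*"``) when a class
    accumulated no synonymous changes.
    """
    unassigned = [c.branch_id for c in counts if c.branch_id not in branch_class_map]
    if unassigned:
        raise ValueError(f"branches without a class: {unassigned[:5]}")
    by_class: dict[str, list[BranchCounts]] = {}
    for c in counts:
        by_class.setdefault(branch_class_map[c.branch_id], []).append(c)
    reports = [
        _pool(members, "lineage-class", label)
        for label, members in sorted(by_class.items())
    ]
    reports.append(_pool(list(counts), "tree", "tree"))
    return reports


def tree_omega(counts: Sequence[BranchCounts]) -> OmegaReport:
    """Tree-wide pooled omega over all branches."""
    return _pool(list(counts), "tree", "tree")


def fraction_branches_omega_gt1(counts: Sequence[BranchCounts]) -> float:
    """Fraction of branches with at least one substitution whose branch
    omega exceeds 1 (undefined-omega branches, Sobs=0 with Nobs>0, count as
    >1; silent branches are excluded)."""
    informative = [c for c in counts if c.n_obs + c.s_obs > 0]
    if not informative:
        return 0.0
    gt1 = 0
    for c in informative:
        if c.s_obs == 0:
            gt1 += c.n_obs > 0
        elif c.omega is not None and c.omega > 1:
            gt1 += 1
    return gt1 / len(informative)


def selection_flag(
    n_nonsyn: float, n_syn: float, threshold: float = 0.5
) -> bool:
    """True when the non-synonymous proportion exceeds the threshold.

    The default 0.5 flags clades where replacements outnumber silent
    changes — the inverted ratio that invalidates synonymous-only dating.
    The boundary itself (exactly the threshold) is not flagged.
    """
    total = n_nonsyn + n_syn
    if total <= 0:
        raise ValueError("clade has no substitutions")
    return (n_nonsyn / total) > threshold


def branch_frame(counts: Sequence[BranchCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "branch": c.branch_id,
                "n_obs": round(c.n_obs, 3),
                "s_obs": round(c.s_obs, 3),
                "omega": "*" if c.omega is None else round(c.omega, 3),
            }
            for c in counts
        ]
    )


def omega_frame(reports: Sequence[OmegaReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scope": r.scope,
                "label": r.label,
                "n_obs": round(r.n_obs, 3),
                "s_obs": round(r.s_obs, 3),
                "dn": round(r.dn, 5),
                "ds": round(r.ds, 5),
                "omega": r.omega_str,
            }
            for r in reports
        ]
    )
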
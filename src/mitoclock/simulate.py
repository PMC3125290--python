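"""Synthetic-data generator: genealogies, codon sequences, biased sampling.

Generates every input the pipeline consumes, so all stages are testable
without external downloads. Three layers:

1. **Genealogy** — a haploid coalescent under exponential growth (msprime),
   with the published simulation parameters as defaults: 500 sequences of
   3000 nt, mutation rate 1e-4 /site/generation, growth rate 1e-3,
   effective population size 1000.
2. **Sequence evolution** — a per-branch substitution sampler: candidate
   mutations arrive as a Poisson process at the clock rate (times any
   per-lineage rate multiplier), and a candidate is accepted with
   probability min(1, omega) if non-synonymous or min(1, 1/omega) if
   synonymous, under the branch's lineage-class omega. Stop-codon-creating
   candidates are rejected and redrawn (logged). The true event log is
   retained as ground truth.
3. **Ascertained sampling** — the variance-ranking / pseudo-haplogroup
   protocol: rank segregating sites by allele-frequency variance, split the
   population by the top-variance sites into pseudo-haplogroups, then draw
   either a uniform random sample or an "ascertained" sample allocated
   proportionally to pseudo-haplogroup frequencies (largest-remainder
   rounding).

All randomness flows from one integer seed; outputs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import msprime
import numpy as np
import pandas as pd
import yaml

from .genetic_code import (
    BASES,
    CodingAnnotation,
    MutationClass,
    Substitution,
    VERTEBRATE_MITO,
    classify_substitution,
    single_gene_annotation,
    translate_codon,
)
from .haplotree import BranchEvent, HaplotypeTree, Node, build_tree

logger = logging.getLogger("mitoclock")

#: generation-to-year scaling used when dating simulated clades
GENERATION_YEARS = 25.0


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated population (defaults = study conditions)."""

    n_sequences: int = 500
    seq_length: int = 3000  # nucleotides, multiple of 3
    mutation_rate: float = 1.0e-4  # per site per generation
    omega_map: Mapping[str, float] = field(default_factory=lambda: {"default": 1.0})
    rate_multiplier_map: Mapping[str, float] = field(default_factory=dict)
    growth_rate: float = 1.0e-3
    effective_pop_size: float = 1000.0
    seed: int = 1
    code_id: int = VERTEBRATE_MITO

    def __post_init__(self) -> None:
        if self.seq_length % 3:
            raise ValueError("seq_length must be a multiple of 3")
        if self.mutation_rate < 0 or any(v < 0 for v in self.omega_map.values()):
            raise ValueError("rates must be non-negative")


@dataclass
class SimEvent:
    """One accepted substitution, with its ground-truth classification."""

    branch: str  # child node id
    position: int  # 1-based
    ref: str
    alt: str
    mutation_class: MutationClass


@dataclass
class SimResult:
    tree: HaplotypeTree
    node_sequences: dict[str, str]
    events: list[SimEvent]
    scenario: SimScenario

    @property
    def tip_sequences(self) -> dict[str, str]:
        return {t.node_id: self.node_sequences[t.node_id] for t in self.tree.tips}

    def event_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "branch": e.branch,
                    "position": e.position,
                    "ref": e.ref,
                    "alt": e.alt,
                    "class": e.mutation_class.value,
                }
                for e in self.events
            ]
        )


# ----------------------------------------------------------------- genealogy
def simulate_genealogy(scenario: SimScenario) -> HaplotypeTree:
    """Haploid coalescent genealogy under exponential growth.

    Branch lengths are in generations; tips are named ``t0..t{n-1}``,
    internal nodes ``n<k>``. Deterministic under the scenario seed.
    """
    if scenario.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    demography = msprime.Demography()
    demography.add_population(
        initial_size=scenario.effective_pop_size,
        growth_rate=scenario.growth_rate,
        name="pop",
    )
    ts = msprime.sim_ancestry(
        samples={"pop": scenario.n_sequences},
        demography=demography,
        ploidy=1,
        random_seed=(scenario.seed % (2**31 - 1)) + 1,
    )
    t = ts.first()
    nodes: dict[int, Node] = {}

    def convert(u: int) -> Node:
        children = t.children(u)
        name = f"t{u}" if not children else f"n{u}"
        node = Node(name)
        for c in children:
            child = convert(c)
            child.parent = node
            child.length = t.branch_length(c)
            node.children.append(child)
        nodes[u] = node
        return node

    root = convert(t.root)
    root.label = "MRCA"
    return HaplotypeTree(root)


def tmrca_generations(tree: HaplotypeTree) -> float:
    """Root age in generations (max root-to-tip branch-length sum; equal
    across tips for coalescent genealogies)."""
    best = 0.0
    for tip in tree.tips:
        d, cur = 0.0, tip
        while cur.parent is not None:
            d += cur.length or 0.0
            cur = cur.parent
        best = max(best, d)
    return best


# ---------------------------------------------------------------- evolution
def random_root_sequence(
    length: int, rng: np.random.Generator, code_id: int = VERTEBRATE_MITO
) -> str:
    """Uniform codon usage over non-stop codons."""
    codons = [
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if translate_codon(a + b + c, code_id) != "*"
    ]
    return "".join(rng.choice(codons, size=length // 3))


def evolve_sequences(
    tree: HaplotypeTree,
    scenario: SimScenario,
    annotation: CodingAnnotation | None = None,
    branch_class_map: Mapping[str, str] | None = None,
    root_sequence: str | None = None,
) -> SimResult:
    """Evolve codon sequences down a genealogy with per-class omega and rate.

    Candidate substitutions arrive as Poisson(mu * L * branch_length *
    rate_multiplier); each candidate proposes a uniform site and a uniform
    alternative base, is redrawn if it would create a stop codon, and is
    then accepted with probability min(1, omega) when non-synonymous or
    min(1, 1/omega) when synonymous. Accepted events are appended to the
    tree's branch event lists and logged as ground truth.
    """
    annotation = annotation or single_gene_annotation(
        scenario.seq_length, code_id=scenario.code_id
    )
    branch_class_map = branch_class_map or {}
    rng = np.random.default_rng(scenario.seed)
    L = scenario.seq_length
    if root_sequence is None:
        root_sequence = random_root_sequence(L, rng, scenario.code_id)
    if len(root_sequence) != L:
        raise ValueError("root sequence length mismatch")

    default_omega = scenario.omega_map.get("default", 1.0)
    node_sequences: dict[str, list[str]] = {}
    events: list[SimEvent] = []
    node_sequences[tree.root.node_id] = list(root_sequence)

    for node in tree.preorder():
        if node.parent is None:
            continue
        seq = list(node_sequences[node.parent.node_id])
        cls = branch_class_map.get(node.node_id, "default")
        mult = scenario.rate_multiplier_map.get(cls, 1.0)
        omega = scenario.omega_map.get(cls, default_omega)
        lam = scenario.mutation_rate * L * (node.length or 0.0) * mult
        n_candidates = rng.poisson(lam)
        for _ in range(n_candidates):
            for _attempt in range(100):
                pos = int(rng.integers(L)) + 1
                ref = seq[pos - 1]
                # uniform over the 3 non-identical bases
                alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
                ctx = annotation.codon_context(pos, seq)
                sub = Substitution(pos, ref, alt)
                if ctx is None:
                    mclass = classify_substitution(sub, None, annotation)
                else:
                    mclass = classify_substitution(
                        sub, ctx[0], annotation, offset=ctx[1]
                    )
                if mclass is MutationClass.NONSENSE:
                    logger.debug("stop-creating candidate at %d redrawn", pos)
                    continue
                break
            else:
                continue  # could not place a non-stop candidate; drop it
            if mclass is MutationClass.SYNONYMOUS:
                p_accept = min(1.0, 1.0 / omega) if omega > 0 else 1.0
            else:
                p_accept = min(1.0, omega)
            if rng.random() >= p_accept:
                continue
            seq[pos - 1] = alt
            node.events.append(BranchEvent(sub, mclass))
            events.append(SimEvent(node.node_id, pos, ref, alt, mclass))
        node_sequences[node.node_id] = seq
    return SimResult(
        tree, {k: "".join(v) for k, v in node_sequences.items()}, events, scenario
    )


# ----------------------------------------------------------------- sampling
def variance_rank_sites(alignment: Mapping[str, str]) -> list[tuple[int, float]]:
    """Segregating sites ranked by allele-frequency variance.

    The score per site is the expected heterozygosity 1 - sum(p_a^2): a
    50/50 biallelic split is maximal, a 95/5 split low. Monomorphic sites
    are omitted; an entirely monomorphic alignment yields an empty ranking.
    Invariant under sequence order.
    """
    seqs = list(alignment.values())
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    scores: list[tuple[int, float]] = []
    for j in range(mat.shape[1]):
        _vals, counts = np.unique(mat[:, j], return_counts=True)
        if counts.size < 2:
            continue
        p = counts / counts.sum()
        scores.append((j + 1, float(1.0 - np.sum(p**2))))
    scores.sort(key=lambda t: (-t[1], t[0]))
    return scores


@dataclass
class Grouping:
    """Pseudo-haplogroup assignment from top-variance sites."""

    assignments: dict[str, str]  # sequence id -> group key
    sites_used: list[int]
    ok: bool  #: True when the >=min_groups x >=min_size criterion was met

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, g in self.assignments.items():
            out.setdefault(g, []).append(sid)
        return out


def pseudo_haplogroup_split(
    alignment: Mapping[str, str],
    ranked_sites: Sequence[tuple[int, float]] | None = None,
    min_groups: int = 5,
    min_size: int = 20,
) -> Grouping:
    """Split the population by joint alleles at successive top-variance sites.

    Sites are added in ranking order; after each addition the population is
    partitioned by the joint allele pattern at the selected sites. Stops at
    the first prefix giving at least ``min_groups`` groups of at least
    ``min_size`` members each. If no prefix achieves that, the prefix
    maximising the number of adequately-sized groups is returned with
    ``ok=False`` (a flagged partial grouping, never silently accepted).
    """
    if ranked_sites is None:
        ranked_sites = variance_rank_sites(alignment)
    if not ranked_sites:
        raise ValueError("no segregating sites to split on")
    ids = list(alignment)
    best: tuple[int, int] | None = None  # (n adequate groups, -k)
    best_assign: dict[str, str] = {}
    best_sites: list[int] = []
    for k in range(1, len(ranked_sites) + 1):
        sites = [pos for pos, _ in ranked_sites[:k]]
        assign = {
            sid: "".join(alignment[sid][p - 1] for p in sites) for sid in ids
        }
        sizes = pd.Series(list(assign.values())).value_counts()
        adequate = int((sizes >= min_size).sum())
        if adequate >= min_groups:
            return Grouping(assign, sites, ok=True)
        if best is None or (adequate, -k) > best:
            best = (adequate, -k)
            best_assign, best_sites = assign, sites
    logger.warning(
        "pseudo-haplogroup criterion unreachable: best %d groups >= %d members",
        best[0], min_size,
    )
    return Grouping(best_assign, best_sites, ok=False)


def draw_sample(
    grouping: Grouping,
    design: str,
    size: int,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw a sequence subset: ``"random"`` uniformly over the population,
    ``"ascertained"`` allocated to pseudo-haplogroups proportionally to
    their frequencies (largest-remainder rounding; a group smaller than its
    allocation contributes all members and the shortfall is reallocated),
    then uniformly within each group."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    population = sorted(grouping.assignments)
    if size > len(population):
        raise ValueError("sample size exceeds population")
    if design == "random":
        return sorted(rng.choice(population, size=size, replace=False).tolist())
    if design != "ascertained":
        raise ValueError(f"unknown design {design!r}")
    groups = {g: sorted(m) for g, m in grouping.groups.items()}
    labels = sorted(groups)
    n_total = len(population)
    quotas = {g: size * len(groups[g]) / n_total for g in labels}
    alloc = {g: int(np.floor(quotas[g])) for g in labels}
    remainders = sorted(
        labels, key=lambda g: (-(quotas[g] - alloc[g]), g)
    )
    short = size - sum(alloc.values())
    for g in remainders[:short]:
        alloc[g] += 1
    # cap at group size, reallocate overflow by next-largest remainders
    overflow = 0
    for g in labels:
        if alloc[g] > len(groups[g]):
            overflow += alloc[g] - len(groups[g])
            alloc[g] = len(groups[g])
    while overflow > 0:
        candidates = [g for g in remainders if alloc[g] < len(groups[g])]
        if not candidates:
            raise ValueError("cannot place sample: population exhausted")
        alloc[candidates[0]] += 1
        overflow -= 1
    out: list[str] = []
    for g in labels:
        if alloc[g] == 0:
            continue
        out.extend(rng.choice(groups[g], size=alloc[g], replace=False).tolist())
    return sorted(out)


# ----------------------------------------------------------------- fixtures
SCENARIOS = ("recodon_default", "r0_slow", "j_selection", "table5_shape")


def _largest_root_child(tree: HaplotypeTree) -> Node:
    return max(tree.root.children, key=lambda c: len(tree.tips_below(c)))


def clade_class_map(
    tree: HaplotypeTree, clade_root: Node, class_name: str, stems_only: bool = False
) -> dict[str, str]:
    """Assign ``class_name`` to a clade's branches: the clade stem plus all
    branches below it (or, with ``stems_only``, the stem and the branches
    from the clade MRCA to each child — the "stems" of its radiation)."""
    out = {clade_root.node_id: class_name}
    if stems_only:
        for c in clade_root.children:
            out[c.node_id] = class_name
        return out
    stack = list(clade_root.children)
    while stack:
        n = stack.pop()
        out[n.node_id] = class_name
        stack.extend(n.children)
    return out


def simulate_scenario(name: str, seed: int = 1, **overrides) -> SimResult:
    """Run a named simulation scenario end to end (genealogy + sequences).

    ``recodon_default``: neutral baseline at the published parameters.
    ``r0_slow``: the largest root-child clade evolves at a 0.5 clock
    multiplier over its whole history (class ``slow``).
    ``j_selection``: the largest root-child clade's stem branches carry
    omega 1.2 (class ``stems``), the background omega 0.05 elsewhere being
    left at 1 so the contrast is attributable to the stems.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; registry: {SCENARIOS}")
    if name == "table5_shape":
        raise ValueError("table5_shape is a deterministic tree fixture; "
                         "use make_fixture or table5_tree()")
    if name == "recodon_default":
        scenario = SimScenario(seed=seed, **overrides)
        tree = simulate_genealogy(scenario)
        return evolve_sequences(tree, scenario)
    if name == "r0_slow":
        scenario = SimScenario(
            seed=seed, rate_multiplier_map={"slow": 0.5}, **overrides
        )
        tree = simulate_genealogy(scenario)
        clade = _largest_root_child(tree)
        tree.set_label(clade.node_id, "SLOW")
        cmap = clade_class_map(tree, clade, "slow")
        return evolve_sequences(tree, scenario, branch_class_map=cmap)
    # j_selection
    scenario = SimScenario(
        seed=seed, omega_map={"default": 1.0, "stems": 1.2}, **overrides
    )
    tree = simulate_genealogy(scenario)
    clade = _largest_root_child(tree)
    tree.set_label(clade.node_id, "J")
    cmap = clade_class_map(tree, clade, "stems", stems_only=True)
    return evolve_sequences(tree, scenario, branch_class_map=cmap)


#: Archetypes of the replacement mutations carried on a selected clade's
#: stems (fixture annotation labels in gene:aa-change form).
J_RADIATION_ARCHETYPES = (
    "ND3:T114A", "ND5:A458T", "CYTB:L236I", "CYTB:F18L", "CYTB:D171N",
    "CYTB:V352M",
)


def table5_tree() -> tuple[HaplotypeTree, dict[str, str]]:
    """Deterministic dating fixture: clades whose per-tip synonymous counts
    reproduce the published per-clade means (anchor clade mean 8.26, slow
    clade 2.89 with a depth-1 MRCA, a nested subclade at 2.00, and a
    selection-flagged clade with a 60% replacement fraction).

    Returns (tree, partition mapping clade label -> MRCA node id).
    """
    rows: list[tuple[str, str, str]] = []

    def syn_events(n: int, start_pos: int) -> str:
        # distinct third-position-style tokens; classes are supplied
        # explicitly so positions only need to be unique
        return ";".join(f"A{start_pos + 3 * i}G" for i in range(n))

    pos = [100]

    def events(n: int) -> str:
        s = syn_events(n, pos[0])
        pos[0] += 3 * n + 3
        return s

    # anchor clade: 50 tips, counts 37x8 + 13x9 -> mean 8.26
    rows.append(("MRCA_GLOBAL", "MRCA_R", ""))
    counts = [8] * 37 + [9] * 13
    for i, c in enumerate(counts):
        rows.append((f"g{i}", "MRCA_GLOBAL", events(c)))
    # slow clade: MRCA 1 synonymous step below root; 50 tips of 2 (nested
    # subclade, mean 2.00) + 39x4 + 11x3 -> overall mean 2.89
    rows.append(("MRCA_R0", "MRCA_R", events(1)))
    rows.append(("MRCA_H", "MRCA_R0", ""))
    for i in range(50):
        rows.append((f"h{i}", "MRCA_H", events(2)))
    for i, c in enumerate([4] * 39 + [3] * 11):
        rows.append((f"r0_{i}", "MRCA_R0", events(c)))
    base = build_tree(pd.DataFrame(rows, columns=["child", "parent", "substitutions"]))
    # selection-flagged clade: 20 tips, 2 syn + 3 nonsyn each (60% replacement)
    jroot = Node("MRCA_J", parent=base.root)
    base.root.children.append(jroot)
    p = 15000
    for i in range(20):
        tip = Node(f"j{i}", parent=jroot)
        jroot.children.append(tip)
        for _ in range(2):
            tip.events.append(
                BranchEvent(Substitution(p, "A", "G"), MutationClass.SYNONYMOUS)
            )
            p += 1
        for _ in range(3):
            tip.events.append(
                BranchEvent(Substitution(p, "A", "G"), MutationClass.NONSYNONYMOUS)
            )
            p += 1
    for node_id in list(base.nodes):
        for ev in base.nodes[node_id].events:
            if ev.mutation_class is None:
                ev.mutation_class = MutationClass.SYNONYMOUS
    partition = {
        "GLOBAL": "MRCA_GLOBAL",
        "R0": "MRCA_R0",
        "H": "MRCA_H",
        "J": "MRCA_J",
    }
    tree = HaplotypeTree(base.root)  # re-index with the added clade
    for label, nid in partition.items():
        tree.node(nid).label = label
    tree.clades.update({label: nid for label, nid in partition.items()})
    return tree, partition


def make_fixture(named_scenario: str, outdir, seed: int = 1) -> dict[str, Path]:
    """Write a named scenario's file bundle (FASTA + Newick + TSV tables +
    truth log + manifest). Re-running with the same seed is byte-identical.
    Returns a mapping of artefact name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if named_scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {named_scenario!r}; registry: {SCENARIOS}"
        )
    paths: dict[str, Path] = {}
    manifest: dict = {"scenario": named_scenario, "seed": seed}
    if named_scenario == "table5_shape":
        tree, partition = table5_tree()
        paths["branches"] = outdir / "branches.tsv"
        tree.to_tsv(paths["branches"])
        paths["newick"] = outdir / "tree.nwk"
        paths["newick"].write_text(tree.to_newick() + "\n")
        manifest["partition"] = partition
    else:
        result = simulate_scenario(named_scenario, seed=seed)
        paths["branches"] = outdir / "branches.tsv"
        result.tree.to_tsv(paths["branches"])
        paths["newick"] = outdir / "tree.nwk"
        paths["newick"].write_text(result.tree.to_newick() + "\n")
        paths["alignment"] = outdir / "tips.fasta"
        with open(paths["alignment"], "w") as fh:
            for tid, seq in sorted(result.tip_sequences.items()):
                fh.write(f">{tid}\n{seq}\n")
        paths["truth"] = outdir / "truth_events.tsv"
        result.event_frame().to_csv(paths["truth"], sep="\t", index=False)
        manifest["n_events"] = len(result.events)
        manifest["scenario_params"] = {
            "n_sequences": result.scenario.n_sequences,
            "seq_length": result.scenario.seq_length,
            "mutation_rate": result.scenario.mutation_rate,
            "growth_rate": result.scenario.growth_rate,
            "effective_pop_size": result.scenario.effective_pop_size,
            "omega_map": dict(result.scenario.omega_map),
            "rate_multiplier_map": dict(result.scenario.rate_multiplier_map),
        }
        if named_scenario == "j_selection":
            stem_nonsyn = [
                e for e in result.events
                if e.mutation_class is MutationClass.NONSYNONYMOUS
                and e.branch in {c.node_id for c in result.tree.clade_node("J").children}
                | {result.tree.clades["J"]}
            ]
            arch = pd.DataFrame(
                [
                    {
                        "branch": e.branch,
                        "position": e.position,
                        "ref": e.ref,
                        "alt": e.alt,
                        "archetype": J_RADIATION_ARCHETYPES[
                            i % len(J_RADIATION_ARCHETYPES)
                        ],
                    }
                    for i, e in enumerate(stem_nonsyn[: len(J_RADIATION_ARCHETYPES)])
                ],
                columns=["branch", "position", "ref", "alt", "archetype"],
            )
            paths["archetypes"] = outdir / "j_archetypes.tsv"
            arch.to_csv(paths["archetypes"], sep="\t", index=False)
    paths["manifest"] = outdir / "manifest.yaml"
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths

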
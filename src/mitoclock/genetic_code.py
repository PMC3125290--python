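"""Reference-sequence conventions and substitution classification.

Every mutation count in the pipeline rests on this module: the vertebrate
mitochondrial genetic code (ATA=Met, TGA=Trp, AGA/AGG=Stop relative to the
standard code), 1-based inclusive coordinates on the (circular) reference,
and the Nei–Gojobori decomposition of coding positions into fractional
synonymous and non-synonymous sites.

Coordinates are 1-based inclusive throughout; circularity is ignored for
coding spans (none of the analysed genes wrap the origin). Genes on the
light strand are handled by reverse-complementing the codon context before
translation.
"""

from __future__ import annotations

import enum
import json
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger("mitoclock")

#: NCBI genetic-code table ids.
VERTEBRATE_MITO = 2
STANDARD = 1

BASES = ("A", "C", "G", "T")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class MutationClass(enum.Enum):
    """Functional class of a substitution against an annotated reference."""

    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONSENSE = "nonsense"
    NONCODING = "noncoding"
    RRNA_TRNA = "rRNA_tRNA"
    #: ambiguous base or otherwise unclassifiable; excluded from counts
    UNKNOWN = "unknown"
    #: indel inside a coding span; excluded from syn/nonsyn counts
    FRAME_DISRUPTING = "frame_disrupting"


#: Classes counted as "coding" substitutions (Results' synonymous +
#: non-synonymous totals; nonsense events are counted with nonsynonymous).
CODING_CLASSES = frozenset(
    {MutationClass.SYNONYMOUS, MutationClass.NONSYNONYMOUS, MutationClass.NONSENSE}
)


def _code_table(code_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code_id]


def translate_codon(codon: str, code_id: int = VERTEBRATE_MITO) -> str:
    """Translate a codon under the named NCBI code table.

    Returns the one-letter amino acid, ``"*"`` for a stop codon, or ``"X"``
    when the codon contains an ambiguous/non-ACGT base (callers exclude
    such events from counts).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        logger.debug("ambiguous codon %r -> X", codon)
        return "X"
    table = _code_table(code_id)
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substitution_kind(ref_base: str, alt_base: str) -> str:
    """'transition', 'transversion' or 'indel' for a ref/alt base pair."""
    ref, alt = ref_base.upper(), alt_base.upper()
    if ref in ("", "-") or alt in ("", "-") or len(ref) != 1 or len(alt) != 1:
        return "indel"
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    if ref not in BASES or alt not in BASES:
        return "unknown"
    if (ref in _PURINES) == (alt in _PURINES):
        return "transition"
    return "transversion"


@dataclass(frozen=True)
class Substitution:
    """A single mutation event at a 1-based reference coordinate."""

    position: int
    ref_base: str
    alt_base: str

    @property
    def kind(self) -> str:
        return substitution_kind(self.ref_base, self.alt_base)

    @property
    def is_indel(self) -> bool:
        return self.kind == "indel"

    def __str__(self) -> str:  # e.g. "A8701G"
        return f"{self.ref_base}{self.position}{self.alt_base}"

    @classmethod
    def parse(cls, token: str) -> "Substitution":
        """Parse compact tokens like ``A8701G`` or indels ``8281-A`` / ``8281A-``."""
        token = token.strip()
        ref, alt = token[0], token[-1]
        pos = int(token[1:-1])
        return cls(pos, ref, alt)


@dataclass(frozen=True)
class GeneSpan:
    """One annotated feature on the reference (1-based inclusive span)."""

    gene: str
    start: int
    end: int
    strand: str = "heavy"  # heavy | light
    frame_offset: int = 0  # 0..2, offset of the first codon base from `start`
    kind: str = "protein"  # protein | rRNA | tRNA

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.strand not in ("heavy", "light"):
            raise ValueError(f"{self.gene}: bad strand {self.strand!r}")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError(f"{self.gene}: frame_offset out of range")

    @property
    def n_codons(self) -> int:
        return (self.end - self.start + 1 - self.frame_offset) // 3

    def codon_positions(self, codon_index: int) -> tuple[int, int, int]:
        """Reference coordinates of codon ``codon_index`` (0-based), in
        reading order (descending for light-strand genes)."""
        if self.strand == "heavy":
            first = self.start + self.frame_offset + 3 * codon_index
            return (first, first + 1, first + 2)
        first = self.end - self.frame_offset - 3 * codon_index
        return (first, first - 1, first - 2)


class CodingAnnotation:
    """Gene spans + genetic code for classifying substitutions.

    Protein spans must be non-overlapping (classification would otherwise
    be ambiguous) and each span length must be compatible with its declared
    frame; an incomplete terminal codon is allowed but excluded from site
    counts with a warning.
    """

    def __init__(
        self,
        genes: Iterable[GeneSpan],
        code_id: int = VERTEBRATE_MITO,
        exclude_positions: Iterable[int] = (),
    ) -> None:
        self.genes = list(genes)
        self.code_id = code_id
        self.exclude_positions = frozenset(exclude_positions)
        self._check_overlaps()
        # position -> (gene, codon_index, offset in reading order)
        self._index: dict[int, tuple[GeneSpan, int, int]] = {}
        self._rna_positions: dict[int, GeneSpan] = {}
        for g in self.genes:
            if g.kind != "protein":
                for p in range(g.start, g.end + 1):
                    self._rna_positions[p] = g
                continue
            for ci in range(g.n_codons):
                for off, p in enumerate(g.codon_positions(ci)):
                    self._index[p] = (g, ci, off)

    def _check_overlaps(self) -> None:
        spans = sorted(
            ((g.start, g.end, g.gene) for g in self.genes if g.kind == "protein")
        )
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping protein spans: {n1} and {n2}")

    @property
    def protein_genes(self) -> list[GeneSpan]:
        return [g for g in self.genes if g.kind == "protein"]

    @property
    def n_codons(self) -> int:
        return sum(g.n_codons for g in self.protein_genes)

    def locate(self, position: int) -> tuple[GeneSpan, int, int] | None:
        """(gene, codon index, offset-in-codon) at a coding position, else None."""
        return self._index.get(position)

    def region_class(self, position: int) -> MutationClass:
        if position in self._index:
            raise ValueError("coding position; classify with a codon context")
        if position in self._rna_positions:
            return MutationClass.RRNA_TRNA
        return MutationClass.NONCODING

    def codon_context(self, position: int, reference: str) -> tuple[str, int] | None:
        """Reference codon (in reading orientation) and within-codon offset
        covering ``position``; None outside protein genes."""
        hit = self.locate(position)
        if hit is None:
            return None
        gene, ci, off = hit
        bases = [reference[p - 1] for p in gene.codon_positions(ci)]
        codon = "".join(bases)
        if gene.strand == "light":
            codon = "".join(b.translate(_COMPLEMENT) for b in bases)
        return codon.upper(), off

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_tsv(cls, path, **kwargs) -> "CodingAnnotation":
        df = pd.read_csv(path, sep="\t")
        return cls._from_frame(df, **kwargs)

    @classmethod
    def from_json(cls, path, **kwargs) -> "CodingAnnotation":
        with open(path) as fh:
            records = json.load(fh)
        return cls._from_frame(pd.DataFrame(records), **kwargs)

    @classmethod
    def _from_frame(cls, df: pd.DataFrame, **kwargs) -> "CodingAnnotation":
        genes = [
            GeneSpan(
                gene=str(r["gene"]),
                start=int(r["start"]),
                end=int(r["end"]),
                strand=str(r.get("strand", "heavy")),
                frame_offset=int(r.get("frame", r.get("frame_offset", 0)) or 0),
                kind=str(r.get("kind", "protein")),
            )
            for r in df.to_dict("records")
        ]
        return cls(genes, **kwargs)


def classify_substitution(
    sub: Substitution,
    context_codon: str | None,
    annotation: CodingAnnotation,
    offset: int | None = None,
) -> MutationClass:
    """Classify one substitution against the ancestral codon context.

    ``context_codon`` is the ancestral codon containing the site, in the
    gene's reading orientation (i.e. already reverse-complemented for
    light-strand genes — :meth:`CodingAnnotation.codon_context` produces
    it in that form). ``offset`` is the 0-based position of the mutated
    base inside the codon; when omitted it is resolved from the annotation.
    """
    if sub.position in annotation.exclude_positions:
        return MutationClass.UNKNOWN
    hit = annotation.locate(sub.position)
    if hit is None:
        if sub.is_indel:
            return annotation.region_class(sub.position)
        return annotation.region_class(sub.position)
    gene, _ci, off = hit
    if sub.is_indel:
        logger.debug("frame-disrupting indel at %d in %s", sub.position, gene.gene)
        return MutationClass.FRAME_DISRUPTING
    if offset is not None:
        off = offset
    if context_codon is None:
        return MutationClass.UNKNOWN
    ref, alt = sub.ref_base.upper(), sub.alt_base.upper()
    if ref not in BASES or alt not in BASES:
        logger.debug("ambiguous substitution %s excluded", sub)
        return MutationClass.UNKNOWN
    if gene.strand == "light":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    codon = context_codon.upper()
    if codon[off] != ref:
        logger.debug(
            "context mismatch at %d: codon %s offset %d vs ref %s",
            sub.position, codon, off, ref,
        )
    mutated = codon[:off] + alt + codon[off + 1 :]
    aa_ref = translate_codon(codon, annotation.code_id)
    aa_alt = translate_codon(mutated, annotation.code_id)
    if "X" in (aa_ref, aa_alt):
        return MutationClass.UNKNOWN
    if aa_ref == aa_alt:
        return MutationClass.SYNONYMOUS
    if aa_alt == "*":
        return MutationClass.NONSENSE
    return MutationClass.NONSYNONYMOUS


def classify_at(
    position: int,
    ref_base: str,
    alt_base: str,
    reference: str,
    annotation: CodingAnnotation,
) -> MutationClass:
    """Convenience wrapper building the codon context from the reference."""
    sub = Substitution(position, ref_base, alt_base)
    ctx = annotation.codon_context(position, reference)
    if ctx is None:
        return classify_substitution(sub, None, annotation)
    codon, off = ctx
    return classify_substitution(sub, codon, annotation, offset=off)


def codon_site_fractions(codon: str, code_id: int = VERTEBRATE_MITO) -> tuple[float, float]:
    """Nei–Gojobori fractional (synonymous, nonsynonymous) sites of one codon.

    Each of the nine single-base neighbours contributes 1/3 of a site to the
    synonymous pool when the residue is unchanged, otherwise (including
    changes to or from a stop codon) to the non-synonymous pool, so the two
    always sum to 3.
    """
    aa = translate_codon(codon, code_id)
    syn = 0.0
    for off in range(3):
        for b in BASES:
            if b == codon[off]:
                continue
            neighbour = codon[:off] + b + codon[off + 1 :]
            if translate_codon(neighbour, code_id) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@dataclass
class SiteCounts:
    synonymous: float
    nonsynonymous: float

    @property
    def total(self) -> float:
        return self.synonymous + self.nonsynonymous


def count_synonymous_sites(
    annotation: CodingAnnotation, reference_sequence: str
) -> SiteCounts:
    """Nei–Gojobori fractional synonymous/non-synonymous site counts over all
    annotated coding codons of the reference. S + N = 3 x codon count."""
    syn = nonsyn = 0.0
    for gene in annotation.protein_genes:
        if gene.end > len(reference_sequence):
            raise ValueError(
                f"reference shorter than annotated span {gene.gene} "
                f"({gene.end} > {len(reference_sequence)})"
            )
        tail = (gene.end - gene.start + 1 - gene.frame_offset) % 3
        if tail:
            warnings.warn(
                f"{gene.gene}: incomplete terminal codon ({tail} nt) excluded",
                stacklevel=2,
            )
        for ci in range(gene.n_codons):
            bases = [reference_sequence[p - 1] for p in gene.codon_positions(ci)]
            codon = "".join(bases).upper()
            if gene.strand == "light":
                codon = "".join(b.translate(_COMPLEMENT) for b in bases).upper()
            s, n = codon_site_fractions(codon, annotation.code_id)
            syn += s
            nonsyn += n
    return SiteCounts(syn, nonsyn)


def collapse_third_positions(sequence: str, annotation: CodingAnnotation) -> str:
    """Concatenate third-codon-position bases in gene order.

    Bases are reported in each gene's reading orientation (complemented for
    light-strand genes); output length equals the total codon count. Used to
    build the synonymous-signal alignments fed to Bayesian tree searches.
    """
    out: list[str] = []
    for gene in annotation.protein_genes:
        if gene.end > len(sequence):
            raise ValueError(
                f"sequence shorter than annotated span {gene.gene}"
            )
        for ci in range(gene.n_codons):
            third = gene.codon_positions(ci)[2]
            base = sequence[third - 1]
            if gene.strand == "light":
                base = base.translate(_COMPLEMENT)
            out.append(base)
    return "".join(out)


def single_gene_annotation(
    length: int, code_id: int = VERTEBRATE_MITO, gene: str = "sim"
) -> CodingAnnotation:
    """A whole-sequence single-ORF annotation (simulator convenience)."""
    if length % 3:
        raise ValueError("length must be a multiple of 3")
    return CodingAnnotation([GeneSpan(gene, 1, length)], code_id=code_id)
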
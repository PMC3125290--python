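"""HVS1 sequence-quality metrics.

Control-region datasets are screened by splitting observed transitions into
"speedy" sites (fast, frequently recurrent positions) and "weighty" sites
(slow positions, where a call is more informative but an error is more
suspicious), and comparing weighty transitions with the pooled
transversions-plus-indels count. The WTTI ratio (weighty transitions over
transversions + indels) sits in a characteristic band for clean datasets
and explodes for error-ridden ones. The speedy/weighty site partition is an
external data file; a synthetic default is provided for testing only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .genetic_code import substitution_kind

#: inclusive HVS1 analysis window (1-based rCRS coordinates)
DEFAULT_WINDOW = (16090, 16383)
#: full HVS1 span a site-class table must cover
HVS1_SPAN = (16024, 16383)

#: WTTI band observed across curated good-quality datasets, and the value
#: characteristic of a known poor-quality set.
GOOD_QUALITY_BAND = (2.3, 4.8)
POOR_QUALITY_WTTI = 49.0


@dataclass
class QualityCounts:
    speedy_transitions: int
    weighty_transitions: int
    tv_indels: int
    n_excluded: int = 0

    @property
    def wtti(self) -> float:
        return wtti_ratio(self)


class SiteClassTable:
    """Mapping HVS1 position -> {"speedy", "weighty"}; classes disjoint."""

    def __init__(self, classes: Mapping[int, str]):
        bad = {p: c for p, c in classes.items() if c not in ("speedy", "weighty")}
        if bad:
            raise ValueError(f"unknown site classes: {bad}")
        self._classes = dict(classes)

    def __getitem__(self, position: int) -> str:
        try:
            return self._classes[position]
        except KeyError:
            raise KeyError(
                f"HVS1 position {position} has no speedy/weighty classification"
            ) from None

    def __contains__(self, position: int) -> bool:
        return position in self._classes

    @classmethod
    def from_tsv(cls, path) -> "SiteClassTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["position"].astype(int), df["class"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self._classes.items()), columns=["position", "class"]
        ).to_csv(path, sep="\t", index=False)


def synthetic_site_class_table(
    span: tuple[int, int] = HVS1_SPAN, weighty_every: int = 4
) -> SiteClassTable:
    """A synthetic speedy/weighty partition for testing.

    Deterministically marks every ``weighty_every``-th position weighty
    (~25% weighty, the rough proportion seen in published filters). This is
    a stand-in fixture, not the published site classification — analyses of
    real data must supply the published table as a TSV.
    """
    lo, hi = span
    return SiteClassTable(
        {
            p: ("weighty" if p % weighty_every == 0 else "speedy")
            for p in range(lo, hi + 1)
        }
    )


def classify_hvs1_variants(
    variants: pd.DataFrame | Iterable[tuple],
    site_class_table: SiteClassTable,
    window: tuple[int, int] = DEFAULT_WINDOW,
    per_occurrence: bool = True,
) -> QualityCounts:
    """Split HVS1 variants into speedy/weighty transitions and pooled
    transversions+indels.

    ``variants`` is a DataFrame (or iterable of tuples) with columns
    ``haplotype, position, ref, alt`` and optionally ``kind``; rows outside
    the analysis window are excluded (counted in ``n_excluded``).
    Transversions and indels are pooled regardless of site class. With
    ``per_occurrence=False``, repeated observations of the same
    (position, ref, alt) across haplotypes count once.
    """
    if not isinstance(variants, pd.DataFrame):
        variants = pd.DataFrame(
            variants, columns=["haplotype", "position", "ref", "alt"]
        )
    speedy = weighty = tv_indels = excluded = 0
    seen: set[tuple] = set()
    for row in variants.to_dict("records"):
        pos = int(row["position"])
        if not window[0] <= pos <= window[1]:
            excluded += 1
            continue
        if not per_occurrence:
            key = (pos, row["ref"], row["alt"])
            if key in seen:
                continue
            seen.add(key)
        kind = row.get("kind") or substitution_kind(str(row["ref"]), str(row["alt"]))
        if kind == "transition":
            cls = site_class_table[pos]  # KeyError names the position
            if cls == "speedy":
                speedy += 1
            else:
                weighty += 1
        else:  # transversion or indel, pooled
            tv_indels += 1
    return QualityCounts(speedy, weighty, tv_indels, excluded)


def wtti_ratio(counts: QualityCounts) -> float:
    """Weighty transitions / (transversions + indels).

    When no transversions or indels were observed the ratio is undefined;
    ``inf`` is returned if weighty transitions exist (an
    "infinitely clean" sentinel) and ``nan`` for an empty dataset.
    """
    if counts.tv_indels > 0:
        return counts.weighty_transitions / counts.tv_indels
    if counts.weighty_transitions > 0:
        return math.inf
    return math.nan


def in_good_quality_band(
    wtti: float, band: tuple[float, float] = GOOD_QUALITY_BAND
) -> bool:
    return band[0] <= wtti <= band[1]
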
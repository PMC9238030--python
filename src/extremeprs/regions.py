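"""Breast/ovarian cancer cluster-region annotation for BRCA1/2 variants.

Pathogenic variants in BRCA1 and BRCA2 confer relatively higher breast or
ovarian cancer risk depending on where in the coding sequence they fall
(Rebbeck-style cluster regions).  This module carries the region intervals as
1-based inclusive c. coordinates and classifies a variant by closed-interval
overlap of its altered-nucleotide extent with those regions.

Note the BRCA2 regions genuinely overlap each other (BCCR c.7394-8904 and
OCCR c.6645-7471 share c.7394-7471), so a variant there is inside both a BCCR
and an OCCR; the two flags are independent covariates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

Interval = tuple[int, int]


@dataclass(frozen=True)
class ClusterRegionSet:
    """Breast (BCCR) and ovarian (OCCR) cancer cluster regions of one gene."""

    gene: str
    transcript: str
    bccr: tuple[Interval, ...]
    occr: tuple[Interval, ...]

    def __post_init__(self) -> None:
        for start, end in self.bccr + self.occr:
            if not (1 <= start <= end):
                raise ValueError(f"{self.gene}: malformed interval ({start}, {end})")


_BUILTIN = {
    "BRCA1": ClusterRegionSet(
        gene="BRCA1",
        transcript="NM_007294.4",
        bccr=((179, 505), (4328, 4945), (5261, 5563)),
        occr=((1380, 4062),),
    ),
    "BRCA2": ClusterRegionSet(
        gene="BRCA2",
        transcript="NM_000059.4",
        bccr=((1, 596), (772, 1806), (7394, 8904)),
        occr=((3249, 5681), (6645, 7471)),
    ),
}


def builtin_regions() -> dict[str, ClusterRegionSet]:
    """The built-in BRCA1/2 cluster-region definitions, keyed by gene."""
    return dict(_BUILTIN)


def _overlaps(c_start: int, c_end: int, intervals: tuple[Interval, ...]) -> bool:
    return any(c_start <= end and start <= c_end for start, end in intervals)


def classify_variant_region(gene: str, c_start: int, c_end: int,
                            regions: dict[str, ClusterRegionSet] | None = None
                            ) -> tuple[bool, bool]:
    """Classify a variant's extent against its gene's cluster regions.

    The variant extent is the altered reference nucleotides only: a nonsense
    SNV is a 1-bp interval, a deletion spans exactly its deleted bases; the
    truncated downstream sequence is not part of the variant.

    Returns ``(in_bccr, in_occr)``; both may be False, and both may be True
    for variants spanning (or, in BRCA2, sitting inside) overlapping regions.
    """
    if not (1 <= c_start <= c_end):
        raise ValueError(f"invalid variant interval ({c_start}, {c_end})")
    regions = _BUILTIN if regions is None else regions
    if gene not in regions:
        raise KeyError(f"unknown gene {gene!r}")
    rset = regions[gene]
    return _overlaps(c_start, c_end, rset.bccr), _overlaps(c_start, c_end, rset.occr)
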
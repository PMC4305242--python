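"""Marker calling: queen hetSNP candidates, the four filters, CNV screening.

A *marker* is a queen-heterozygous biallelic SNV that survived four
filters: (1) it is a heterozygous single-nucleotide call in the queen
(indels and multiallelic sites are ignored); (2) no drone is heterozygous
at the site (haploid drones should never be het -- clustered het calls
betray multi-copy regions); (3) every non-missing drone allele is one of
the two queen alleles; (4) call quality is at least ``min_qual`` (30).

Multi-copy (CNV) regions are detected from the pooled drone hetSNP sites:
a region is >=2 consecutive het sites with every gap between neighbours
<=2 kb; such regions are masked from standard event calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._alleles import HET, MISSING, decode_base
from .simulate import Colony

__all__ = [
    "MarkerCallingError",
    "DiscardReport",
    "call_candidates",
    "apply_filters",
    "filter_colony",
    "detect_multicopy",
    "heterozygosity",
    "mean_marker_spacing",
]

logger = logging.getLogger(__name__)

_SNV = frozenset("ACGT")


class MarkerCallingError(RuntimeError):
    """Raised when filtering leaves no usable markers."""


@dataclass
class DiscardReport:
    """Per-filter removal counts, in order of application."""

    n_input: int = 0
    not_heterozygous: int = 0
    indel_or_multiallelic: int = 0
    malformed: int = 0
    drone_het: int = 0          # filter 2
    allele_mismatch: int = 0    # filter 3
    low_quality: int = 0        # filter 4
    too_missing: int = 0
    n_markers: int = 0

    def as_dict(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.__dict__.items()}


def call_candidates(queen_table: pd.DataFrame) -> tuple[pd.DataFrame, DiscardReport]:
    """Select queen-heterozygous biallelic SNV sites as marker candidates.

    ``queen_table`` needs columns chrom, pos, allele_a, allele_b, qual.
    Homozygous sites, indels (any allele longer than one base) and
    non-nucleotide alleles are dropped and counted.
    """
    report = DiscardReport(n_input=len(queen_table))
    a = queen_table["allele_a"].astype(str).str.upper()
    b = queen_table["allele_b"].astype(str).str.upper()
    snv = a.isin(_SNV) & b.isin(_SNV)
    malformed = (
        queen_table["pos"].isna()
        | a.isin({"", "."})
        | b.isin({"", "."})
    )
    het = (a != b) & snv
    report.malformed = int(malformed.sum())
    report.indel_or_multiallelic = int((~snv & ~malformed).sum())
    report.not_heterozygous = int(((a == b) & snv & ~malformed).sum())
    out = queen_table.loc[het & ~malformed].copy()
    out["allele_a"] = a[het & ~malformed]
    out["allele_b"] = b[het & ~malformed]
    logger.info(
        "candidates: %d of %d sites (dropped %d hom, %d indel/multiallelic, %d malformed)",
        len(out), report.n_input, report.not_heterozygous,
        report.indel_or_multiallelic, report.malformed,
    )
    return out.reset_index(drop=True), report


def apply_filters(
    colony: Colony,
    min_qual: float = 30.0,
    min_nonmissing_fraction: float = 0.5,
) -> tuple[dict[str, np.ndarray], DiscardReport]:
    """Apply drone-based filters (2)-(4) to the colony's candidate sites.

    Returns a boolean keep-mask per chromosome over the queen marker sites
    plus a :class:`DiscardReport` partitioning the removals (each site is
    attributed to the first filter, in order 2, 3, 4, that rejects it).
    """
    report = DiscardReport(n_input=colony.queen.n_markers)
    keep: dict[str, np.ndarray] = {}
    for chrom in colony.queen.chrom_names:
        codes = colony.drone_alleles[chrom]          # (n_drones, n_sites)
        alleles = colony.queen.alleles[chrom]
        qual = colony.queen.quality[chrom]
        any_het = (codes == HET).any(axis=0)
        observed = codes >= 0
        mismatch = (
            observed
            & (codes != alleles[np.newaxis, :, 0])
            & (codes != alleles[np.newaxis, :, 1])
        ).any(axis=0)
        low_q = qual < min_qual
        informative = observed | (codes == HET)
        too_missing = informative.mean(axis=0) < min_nonmissing_fraction

        bad2 = any_het
        bad3 = ~bad2 & mismatch
        bad4 = ~bad2 & ~mismatch & low_q
        badm = ~bad2 & ~mismatch & ~low_q & too_missing
        report.drone_het += int(bad2.sum())
        report.allele_mismatch += int(bad3.sum())
        report.low_quality += int(bad4.sum())
        report.too_missing += int(badm.sum())
        keep[chrom] = ~(bad2 | bad3 | bad4 | badm)
    report.n_markers = int(sum(m.sum() for m in keep.values()))
    if report.n_markers == 0:
        raise MarkerCallingError("all candidate markers removed; cannot phase")
    return keep, report


def filter_colony(
    colony: Colony,
    min_qual: float = 30.0,
    min_nonmissing_fraction: float = 0.5,
) -> tuple["FilteredMarkers", DiscardReport]:
    """Convenience wrapper: apply filters and materialize the marker set."""
    keep, report = apply_filters(colony, min_qual, min_nonmissing_fraction)
    return FilteredMarkers.from_colony(colony, keep), report


@dataclass
class FilteredMarkers:
    """Retained markers with drone/worker observations restricted to them."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    positions: dict[str, np.ndarray]
    alleles: dict[str, np.ndarray]
    quality: dict[str, np.ndarray]
    drone_alleles: dict[str, np.ndarray]
    worker_alleles: dict[str, np.ndarray]
    keep_mask: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @classmethod
    def from_colony(cls, colony: Colony, keep: Mapping[str, np.ndarray]) -> "FilteredMarkers":
        queen = colony.queen
        return cls(
            chrom_names=queen.chrom_names,
            chrom_lengths=queen.chrom_lengths,
            positions={c: queen.positions[c][keep[c]] for c in queen.chrom_names},
            alleles={c: queen.alleles[c][keep[c]] for c in queen.chrom_names},
            quality={c: queen.quality[c][keep[c]] for c in queen.chrom_names},
            drone_alleles={c: colony.drone_alleles[c][:, keep[c]] for c in queen.chrom_names},
            worker_alleles={c: colony.worker_alleles[c][:, keep[c], :] for c in queen.chrom_names},
            keep_mask={c: np.asarray(keep[c]) for c in queen.chrom_names},
        )

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chrom_names:
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": self.positions[chrom],
                        "allele_a": [decode_base(c) for c in self.alleles[chrom][:, 0]],
                        "allele_b": [decode_base(c) for c in self.alleles[chrom][:, 1]],
                        "qual": self.quality[chrom],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def detect_multicopy(
    colony: Colony,
    max_gap: int = 2000,
    min_sites: int = 2,
    padding: int = 0,
) -> pd.DataFrame:
    """Chain pooled drone hetSNP sites into multi-copy regions.

    Sites are pooled over drones per chromosome; a region is a maximal run
    of het sites with every inter-site interval <= ``max_gap`` and at least
    ``min_sites`` members. Region boundaries are the first/last member site
    (optionally padded). Columns: chrom, start, end, n_hetsnps, n_drones.
    """
    rows = []
    for chrom in colony.queen.chrom_names:
        codes = colony.drone_alleles[chrom]
        het = codes == HET
        site_has_het = het.any(axis=0)
        pos = colony.queen.positions[chrom][site_has_het]
        support = het.sum(axis=0)[site_has_het]
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            n = e - s + 1
            if n < min_sites:
                continue
            drones = np.flatnonzero(het[:, np.flatnonzero(site_has_het)[s : e + 1]].any(axis=1))
            rows.append(
                (
                    chrom,
                    int(pos[s]) - padding,
                    int(pos[e]) + padding,
                    int(n),
                    int(len(drones)),
                )
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_hetsnps", "n_drones"])
    return df


def multicopy_genome_fraction(regions: pd.DataFrame, genome_length: int) -> float:
    """Fraction of the genome covered by detected multi-copy regions."""
    if len(regions) == 0:
        return 0.0
    spans = (regions["end"] - regions["start"] + 1).clip(lower=0)
    return float(spans.sum() / genome_length)


def heterozygosity(n_markers: int, assembled_length: int) -> float:
    """Marker heterozygosity: markers per non-gap assembled base."""
    if assembled_length <= 0:
        raise ValueError("assembled length must be positive")
    return n_markers / assembled_length


def mean_marker_spacing(assembled_length: float, n_markers: float) -> float:
    """Mean interval between adjacent markers (bp per marker)."""
    if n_markers <= 0:
        raise ValueError("need at least one marker")
    return assembled_length / n_markers
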
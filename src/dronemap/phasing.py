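"""Chromosome-scale queen phasing by majority-vote linkage across drones.

For each pair of adjacent markers there are two possible linkages of the
queen's alleles (e.g. for A/G and C/T, either "A-C, G-T" or "A-T, G-C").
Each drone that is cleanly called at both sites votes for one of them;
because recombination between two markers a few hundred bp apart is rare,
the majority linkage is taken as the queen's, and the minority drones are
the recombinants. Chaining these pairwise decisions left to right yields
the two chromosome haplotypes.

Pairs whose interval contains an assembly gap (run of N) are flagged: long
length-unknown gaps concentrate many crossovers between two adjacent
markers, so the vote can be nearly even there; the majority is still taken
(the conservative rule). Exact ties carry the running phase forward
unchanged and are flagged as unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._alleles import decode_base
from .markers import FilteredMarkers

__all__ = [
    "PhasedHaplotypes",
    "link_adjacent",
    "phase_chromosome",
    "phase_colony",
    "switch_error_rate",
]


@dataclass
class PhasedHaplotypes:
    """Phased queen haplotypes over the retained markers of one chromosome."""

    chrom: str
    positions: np.ndarray          # (n,) 1-based bp
    hap0: np.ndarray               # (n,) int8 allele codes
    hap1: np.ndarray
    n_parallel: np.ndarray         # (n-1,) votes keeping allele-column phase
    n_cross: np.ndarray            # (n-1,) votes crossing it
    tie: np.ndarray                # (n-1,) bool, unresolved links
    gap_adjacent: np.ndarray       # (n-1,) bool, interval spans an N-run
    near_even: np.ndarray          # (n-1,) bool, |margin| <= 1

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    @property
    def resolved_fraction(self) -> float:
        """Fraction of adjacent pairs with a strict majority."""
        if len(self.tie) == 0:
            return 1.0
        return float(1.0 - self.tie.mean())

    def alleles_at(self, i: int) -> tuple[str, str]:
        return decode_base(self.hap0[i]), decode_base(self.hap1[i])


def _allele_index(codes: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Map observed codes to queen-allele index: 0, 1, or -1 (unusable)."""
    idx = np.full(codes.shape, -1, dtype=np.int8)
    idx[codes == alleles[np.newaxis, :, 0]] = 0
    idx[codes == alleles[np.newaxis, :, 1]] = 1
    return idx


def link_adjacent(
    alleles_a: np.ndarray,
    alleles_b: np.ndarray,
    drones_a: np.ndarray,
    drones_b: np.ndarray,
) -> tuple[str, int, int]:
    """Majority linkage decision for one adjacent marker pair.

    ``alleles_*`` are the two queen allele codes at each site and
    ``drones_*`` the per-drone observed codes. Returns
    ``("parallel"|"cross"|"tie", n_parallel, n_cross)`` where "parallel"
    links allele column 0 of site A with allele column 0 of site B.
    """
    ia = _allele_index(drones_a[:, np.newaxis], alleles_a[np.newaxis, :]).ravel()
    ib = _allele_index(drones_b[:, np.newaxis], alleles_b[np.newaxis, :]).ravel()
    valid = (ia >= 0) & (ib >= 0)
    n_par = int(((ia == ib) & valid).sum())
    n_cross = int(((ia != ib) & valid).sum())
    if n_par > n_cross:
        return "parallel", n_par, n_cross
    if n_cross > n_par:
        return "cross", n_par, n_cross
    return "tie", n_par, n_cross


def phase_chromosome(
    positions: np.ndarray,
    alleles: np.ndarray,
    drone_codes: np.ndarray,
    gaps: np.ndarray | None = None,
    chrom: str = "",
) -> PhasedHaplotypes:
    """Phase one chromosome from the drone allele matrix.

    ``alleles`` is (n_sites, 2) queen allele codes, ``drone_codes``
    (n_drones, n_sites). Unresolved (tied) links inherit the running phase
    (no switch) and are flagged.
    """
    n = len(positions)
    if n == 0:
        raise ValueError("no markers to phase")
    idx = _allele_index(drone_codes, alleles)
    valid = (idx[:, :-1] >= 0) & (idx[:, 1:] >= 0)
    eq = idx[:, :-1] == idx[:, 1:]
    n_par = (valid & eq).sum(axis=0).astype(np.int64)
    n_cross = (valid & ~eq).sum(axis=0).astype(np.int64)
    cross_wins = n_cross > n_par
    tie = n_cross == n_par
    near_even = np.abs(n_cross - n_par) <= 1

    # phase of each site relative to site 0: cumulative XOR of cross links
    flips = np.concatenate([[0], np.cumsum(cross_wins.astype(np.int8)) % 2]).astype(np.int8)
    rows = np.arange(n)
    hap0 = alleles[rows, flips]
    hap1 = alleles[rows, 1 - flips]

    gap_adjacent = np.zeros(max(n - 1, 0), dtype=bool)
    if gaps is not None and len(gaps):
        left = positions[:-1]
        right = positions[1:]
        for g0, g1 in np.asarray(gaps).reshape(-1, 2):
            gap_adjacent |= (left < g0) & (right > g1)
    return PhasedHaplotypes(
        chrom=chrom,
        positions=np.asarray(positions),
        hap0=hap0.astype(np.int8),
        hap1=hap1.astype(np.int8),
        n_parallel=n_par,
        n_cross=n_cross,
        tie=tie,
        gap_adjacent=gap_adjacent,
        near_even=near_even,
    )


def phase_colony(
    markers: FilteredMarkers,
    gaps: dict[str, np.ndarray] | None = None,
) -> dict[str, PhasedHaplotypes]:
    """Phase every chromosome of a filtered marker set."""
    out = {}
    for chrom in markers.chrom_names:
        out[chrom] = phase_chromosome(
            markers.positions[chrom],
            markers.alleles[chrom],
            markers.drone_alleles[chrom],
            gaps=None if gaps is None else gaps.get(chrom),
            chrom=chrom,
        )
    return out


def switch_error_rate(phased: PhasedHaplotypes, truth_hap0: np.ndarray) -> float:
    """Haplotype switch-error rate against a truth haplotype.

    ``truth_hap0`` are the allele codes of one truth haplotype at the same
    (retained) marker positions. The rate is the fraction of adjacent
    marker pairs at which the inferred phase flips relative to the truth;
    it is invariant to the hap0/hap1 labeling of either side.
    """
    if len(truth_hap0) != phased.n_markers:
        raise ValueError("truth haplotype length mismatch")
    m = (phased.hap0 != truth_hap0).astype(np.int8)
    if len(m) < 2:
        return 0.0
    return float((m[:-1] != m[1:]).mean())
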
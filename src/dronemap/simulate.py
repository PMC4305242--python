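"""Synthetic honey-bee colonies with a complete recombination truth set.

A colony is one diploid queen, ``n_drones`` haploid drones (each a single
maternal gamete) and ``n_workers`` diploid workers (a fresh maternal gamete
paired with a foreign paternal haplotype). The simulator draws the queen's
two haplotypes over a set of heterozygous marker sites, runs independent
meioses to produce gametes with crossovers (CO) and short gene-conversion
tracts (CO-associated and non-crossover), plants copy-number-variant (CNV)
regions that surface as clustered heterozygous calls in drones, applies
genotyping errors, and records every generative decision in a
:class:`TruthSet` so downstream callers can be scored exactly.

Coordinates are 1-based inclusive base pairs, as in VCF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from ._alleles import HET, MISSING

__all__ = [
    "SimulationConfig",
    "QueenGenome",
    "TruthSet",
    "Colony",
    "simulate_queen",
    "simulate_meiosis",
    "simulate_colony",
    "synthesize_reference",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


def _dist_mean(dist: tuple[str, Mapping[str, float]]) -> float:
    name, params = dist
    if name not in ("geometric", "fixed"):
        raise ConfigurationError(f"unknown distribution {name!r}")
    return float(params["mean"])


def _draw_lengths(dist: tuple[str, Mapping[str, float]], n: int, rng) -> np.ndarray:
    name, params = dist
    mean = float(params["mean"])
    if name == "geometric":
        return rng.geometric(1.0 / mean, size=n).astype(np.int64)
    if name == "fixed":
        return np.full(n, int(round(mean)), dtype=np.int64)
    raise ConfigurationError(f"unknown distribution {name!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic colony.

    Defaults reproduce the published three-colony experiment: a 219.6 Mb,
    16-chromosome genome, one marker per ~314 bp (queen heterozygosity
    ~0.32-0.37%), 0.371 crossovers per Mb per meiosis (37.1 cM/Mb), ~5 NCO
    conversion tracts per meiosis with mean tract length 700 bp, ~13.5% of
    the genome inside multi-copy regions, and 50 kb N-runs for
    length-unknown assembly gaps.
    """

    n_chromosomes: int = 16
    chrom_lengths: tuple[int, ...] = tuple(
        int(mb * 1e6) for mb in datasets.CHROM_LENGTHS_MB
    )
    marker_spacing_mean: float = 314.0
    heterozygosity: float | None = None  # overrides spacing when given
    co_per_mb: float = 0.371
    nco_per_meiosis: float = 5.1
    frac_co_with_conversion: float = 0.08
    frac_complex_conversion: float = 0.10
    tract_len_dist: tuple[str, Mapping[str, float]] = ("geometric", {"mean": 700.0})
    cnv_fraction: float = 0.135
    cnv_region_len_dist: tuple[str, Mapping[str, float]] = (
        "geometric",
        {"mean": 4000.0},
    )
    gap_spec: tuple[tuple[int, int, int], ...] = ()  # (chrom idx, start, N-run length)
    genotype_error_rate: float = 1e-5
    mean_quality: float = 55.0
    sd_quality: float = 12.0
    n_drones: int = 15
    n_workers: int = 6
    #: gamma-interference hook (shape of inter-crossover gamma); None = no
    #: interference, crossovers uniform per bp
    interference_shape: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or len(self.chrom_lengths) != self.n_chromosomes:
            raise ConfigurationError("chrom_lengths must match n_chromosomes")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ConfigurationError("chromosome lengths must be positive")
        if self.marker_spacing() <= 1:
            raise ConfigurationError("marker spacing must exceed 1 bp")
        for rate in (self.co_per_mb, self.nco_per_meiosis, self.genotype_error_rate):
            if rate < 0:
                raise ConfigurationError("rates must be non-negative")
        if not 0 <= self.cnv_fraction < 1:
            raise ConfigurationError("cnv_fraction must be in [0, 1)")
        for frac in (self.frac_co_with_conversion, self.frac_complex_conversion):
            if not 0 <= frac <= 1:
                raise ConfigurationError("fractions must be in [0, 1]")
        _dist_mean(self.tract_len_dist)
        _dist_mean(self.cnv_region_len_dist)

    def marker_spacing(self) -> float:
        """Mean inter-marker spacing in bp (1/heterozygosity if that is set)."""
        if self.heterozygosity is not None:
            if self.heterozygosity <= 0:
                raise ConfigurationError("heterozygosity must be positive")
            return 1.0 / self.heterozygosity
        return float(self.marker_spacing_mean)

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths))

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"Chr{i + 1}" for i in range(self.n_chromosomes))

    def scaled(self, factor: float, **overrides) -> "SimulationConfig":
        """A copy with chromosome lengths scaled by ``factor``.

        Crossover density (per Mb), marker spacing and tract lengths are
        kept, so a 1/11-scale genome (~20 Mb) preserves the per-bp physics
        of the full-size genome at a fraction of the cost.
        """
        lengths = tuple(max(int(length * factor), 50_000) for length in self.chrom_lengths)
        return replace(self, chrom_lengths=lengths, gap_spec=(), **overrides)


@dataclass
class QueenGenome:
    """Queen marker map: positions, allele pairs and the two haplotypes.

    ``alleles[:, 0]`` is the allele carried by haplotype 0 and
    ``alleles[:, 1]`` the one carried by haplotype 1 (the order of the two
    is randomized per site, so haplotype labels carry no information).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    positions: dict[str, np.ndarray]       # 1-based, strictly increasing
    alleles: dict[str, np.ndarray]         # (n_sites, 2) int8 codes
    quality: dict[str, np.ndarray]         # phred-like per site
    gaps: dict[str, np.ndarray]            # (n_gaps, 2) 1-based inclusive N-runs

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def haplotype(self, which: int) -> dict[str, np.ndarray]:
        return {c: a[:, which].copy() for c, a in self.alleles.items()}


@dataclass
class TruthSet:
    """Everything needed to reconstruct and score the emitted genotypes."""

    events: pd.DataFrame          # gamete, chrom, kind, start, end, breakpoint
    cnv_regions: pd.DataFrame     # chrom, start, end, haplotype
    gamete_labels: dict[str, dict[str, np.ndarray]]  # gamete -> chrom -> 0/1 per marker
    error_mask: dict[str, dict[str, np.ndarray]]     # sample -> chrom -> bool per marker
    foreign_haplotypes: dict[str, dict[str, np.ndarray]]  # worker -> chrom -> codes


@dataclass
class Colony:
    """In-memory genotype tables for one simulated colony."""

    config: SimulationConfig
    queen: QueenGenome
    drone_names: tuple[str, ...]
    worker_names: tuple[str, ...]
    drone_alleles: dict[str, np.ndarray]   # chrom -> (n_drones, n_sites) int8
    worker_alleles: dict[str, np.ndarray]  # chrom -> (n_workers, n_sites, 2) int8
    truth: TruthSet
    reference: dict[str, str] | None = None


def simulate_queen(config: SimulationConfig, rng: np.random.Generator | None = None) -> QueenGenome:
    """Draw the queen's marker map and two phased haplotypes.

    Marker positions are a renewal process with geometric inter-marker
    spacings around ``config.marker_spacing()``; each marker carries two
    distinct nucleotides with a phred-like quality score. Markers falling
    inside declared assembly gaps (N-runs) are dropped.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    spacing = config.marker_spacing()
    positions: dict[str, np.ndarray] = {}
    alleles: dict[str, np.ndarray] = {}
    quality: dict[str, np.ndarray] = {}
    gaps: dict[str, np.ndarray] = {
        name: np.empty((0, 2), dtype=np.int64) for name in config.chrom_names
    }
    for chrom_idx, start, run in config.gap_spec:
        name = config.chrom_names[chrom_idx]
        gaps[name] = np.vstack(
            [gaps[name], np.array([[start, start + run - 1]], dtype=np.int64)]
        )

    p = 1.0 / spacing
    for name, length in zip(config.chrom_names, config.chrom_lengths):
        n_expect = int(length * p * 1.2) + 20
        steps = rng.geometric(p, size=n_expect)
        pos = np.cumsum(steps)
        while pos[-1] < length:  # pragma: no cover - rare top-up
            extra = rng.geometric(p, size=n_expect // 4 + 10)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        pos = pos[pos <= length]
        if len(pos) < 2:
            raise ConfigurationError(
                f"{name}: fewer than two markers at spacing {spacing:.0f} bp"
            )
        keep = np.ones(len(pos), dtype=bool)
        for g0, g1 in gaps[name]:
            keep &= ~((pos >= g0) & (pos <= g1))
        pos = pos[keep]
        n = len(pos)
        a0 = rng.integers(0, 4, size=n, dtype=np.int8)
        a1 = ((a0 + rng.integers(1, 4, size=n)) % 4).astype(np.int8)
        positions[name] = pos.astype(np.int64)
        alleles[name] = np.stack([a0, a1], axis=1)
        quality[name] = np.clip(
            rng.normal(config.mean_quality, config.sd_quality, size=n), 1.0, 93.0
        )
    return QueenGenome(
        chrom_names=config.chrom_names,
        chrom_lengths=tuple(config.chrom_lengths),
        positions=positions,
        alleles=alleles,
        quality=quality,
        gaps=gaps,
    )


def _co_positions(length: int, config: SimulationConfig, rng) -> np.ndarray:
    rate = config.co_per_mb * length / 1e6
    if config.interference_shape is None:
        n = rng.poisson(rate)
        return np.sort(rng.integers(1, length + 1, size=n))
    # gamma renewal process: inter-crossover distances ~ Gamma(shape, mean/shape)
    shape = config.interference_shape
    mean_gap = 1e6 / config.co_per_mb if config.co_per_mb > 0 else np.inf
    if not np.isfinite(mean_gap):
        return np.array([], dtype=np.int64)
    out = []
    # random start phase for stationarity
    x = rng.uniform(0, mean_gap)
    while x <= length:
        out.append(int(x))
        x += rng.gamma(shape, mean_gap / shape)
    return np.array(sorted(out), dtype=np.int64)


def simulate_meiosis(
    queen: QueenGenome,
    config: SimulationConfig,
    rng: np.random.Generator,
    gamete: str = "g0",
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """One meiosis: haplotype labels per marker plus the truth event list.

    Crossovers are placed uniformly per bp at ``co_per_mb``; a fraction of
    them carry an adjacent conversion tract (complex tracts leave the
    interleaved double-short-block pattern, simple tracts merge invisibly
    into the crossover breakpoint). NCO tract counts are Poisson with
    genome-wide mean ``nco_per_meiosis``; tract lengths come from
    ``tract_len_dist``.
    """
    genome_length = sum(queen.chrom_lengths)
    labels: dict[str, np.ndarray] = {}
    records: list[tuple] = []
    for name, length in zip(queen.chrom_names, queen.chrom_lengths):
        pos = queen.positions[name]
        breakpoints = _co_positions(length, config, rng)
        tract_flips: list[tuple[int, int]] = []
        for b in breakpoints:
            b = int(b)
            if rng.random() < config.frac_co_with_conversion:
                tract_len = int(_draw_lengths(config.tract_len_dist, 1, rng)[0])
                if rng.random() < config.frac_complex_conversion:
                    # complex: detached tract on the donor side of the breakpoint
                    gap = int(rng.exponential(1000.0)) + 50
                    start = max(b - gap - tract_len, 1)
                    end = min(start + tract_len - 1, length)
                    tract_flips.append((start, end))
                    records.append((gamete, name, "CO_conv_complex", start, end, b))
                    records.append((gamete, name, "CO", b, b, b))
                else:
                    # simple: merges into the breakpoint, invisible in one gamete
                    start = max(b - tract_len, 1)
                    records.append((gamete, name, "CO_conv_simple", start, b - 1, b))
                    records.append((gamete, name, "CO", b, b, b))
            else:
                records.append((gamete, name, "CO", b, b, b))
        n_nco = rng.poisson(config.nco_per_meiosis * length / genome_length)
        for _ in range(n_nco):
            tract_len = int(_draw_lengths(config.tract_len_dist, 1, rng)[0])
            start = int(rng.integers(1, max(length - tract_len, 2)))
            end = min(start + tract_len - 1, length)
            tract_flips.append((start, end))
            records.append((gamete, name, "NCO", start, end, -1))

        start_hap = int(rng.integers(0, 2))
        lab = (start_hap + np.searchsorted(breakpoints, pos, side="right")) % 2
        lab = lab.astype(np.int8)
        for s, e in tract_flips:
            sel = (pos >= s) & (pos <= e)
            lab[sel] ^= 1
        labels[name] = lab
    events = pd.DataFrame(
        records, columns=["gamete", "chrom", "kind", "start", "end", "breakpoint"]
    )
    return labels, events


def _plant_cnv_regions(queen: QueenGenome, config: SimulationConfig, rng) -> pd.DataFrame:
    """Non-overlapping multi-copy intervals covering ~cnv_fraction of the genome.

    Each region is linked to one queen haplotype (the copy carrying the
    duplication): drones inheriting that haplotype locally show clustered
    heterozygous calls at the member marker sites.
    """
    rows = []
    for name, length in zip(queen.chrom_names, queen.chrom_lengths):
        target = config.cnv_fraction * length
        covered = 0
        taken: list[tuple[int, int]] = []
        guard = 0
        while covered < target and guard < 100_000:
            guard += 1
            reg_len = int(_draw_lengths(config.cnv_region_len_dist, 1, rng)[0])
            reg_len = min(reg_len, length // 2)
            start = int(rng.integers(1, max(length - reg_len, 2)))
            end = start + reg_len - 1
            if any(s <= end + 1 and start <= e + 1 for s, e in taken):
                continue
            taken.append((start, end))
            covered += reg_len
            rows.append((name, start, end, int(rng.integers(0, 2))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "haplotype"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


def _apply_drone_errors(
    codes: np.ndarray, alleles: np.ndarray, rate: float, rng
) -> np.ndarray:
    """Symmetric error model: half allele flips, half spurious het calls."""
    mask = rng.random(codes.shape) < rate
    if not mask.any():
        return mask
    flip = rng.random(codes.shape) < 0.5
    both = mask & flip & (codes >= 0)
    # flip to a uniformly chosen different nucleotide
    shift = rng.integers(1, 4, size=codes.shape)
    codes[both] = ((codes[both] + shift[both]) % 4).astype(np.int8)
    codes[mask & ~flip] = HET
    return mask


def simulate_colony(config: SimulationConfig) -> Colony:
    """Simulate a full colony (queen, drones, workers) with its truth set."""
    if config.n_drones < 6:
        warnings.warn(
            "fewer than 6 drones: majority-vote phasing becomes unreliable",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    queen = simulate_queen(config, rng)
    cnv = _plant_cnv_regions(queen, config, rng)

    drone_names = tuple(f"drone{i + 1}" for i in range(config.n_drones))
    worker_names = tuple(f"worker{i + 1}" for i in range(config.n_workers))

    gamete_labels: dict[str, dict[str, np.ndarray]] = {}
    error_mask: dict[str, dict[str, np.ndarray]] = {}
    foreign: dict[str, dict[str, np.ndarray]] = {}
    event_frames: list[pd.DataFrame] = []

    drone_alleles: dict[str, np.ndarray] = {}
    worker_alleles: dict[str, np.ndarray] = {}
    cnv_by_chrom = {c: g[["start", "end", "haplotype"]].to_numpy() for c, g in cnv.groupby("chrom")}

    drone_codes: dict[str, list[np.ndarray]] = {c: [] for c in queen.chrom_names}
    for name in drone_names:
        labels, events = simulate_meiosis(queen, config, rng, gamete=name)
        gamete_labels[name] = labels
        event_frames.append(events)
        error_mask[name] = {}
        for chrom in queen.chrom_names:
            pos = queen.positions[chrom]
            lab = labels[chrom]
            codes = queen.alleles[chrom][np.arange(len(pos)), lab].astype(np.int8)
            # CNV-linked heterozygous calls: reads from both copies pile up
            for s, e, hap in cnv_by_chrom.get(chrom, ()):
                sel = (pos >= s) & (pos <= e) & (lab == hap)
                codes[sel] = HET
            error_mask[name][chrom] = _apply_drone_errors(
                codes, queen.alleles[chrom], config.genotype_error_rate, rng
            )
            drone_codes[chrom].append(codes)
    for chrom in queen.chrom_names:
        drone_alleles[chrom] = np.stack(drone_codes[chrom], axis=0)

    worker_codes: dict[str, list[np.ndarray]] = {c: [] for c in queen.chrom_names}
    for name in worker_names:
        labels, events = simulate_meiosis(queen, config, rng, gamete=name)
        gamete_labels[name] = labels
        event_frames.append(events)
        error_mask[name] = {}
        foreign[name] = {}
        for chrom in queen.chrom_names:
            pos = queen.positions[chrom]
            lab = labels[chrom]
            n = len(pos)
            maternal = queen.alleles[chrom][np.arange(n), lab].astype(np.int8)
            # foreign paternal haplotype: at a segregating site the drone
            # father carries either queen allele with near-equal odds, or a
            # third nucleotide (private paternal variant)
            u = rng.random(n)
            pat = np.where(u < 0.45, queen.alleles[chrom][:, 0], queen.alleles[chrom][:, 1]).astype(np.int8)
            third = ((maternal + rng.integers(1, 4, size=n)) % 4).astype(np.int8)
            pat = np.where(u >= 0.90, third, pat)
            pair = np.stack([maternal, pat], axis=1)
            err = rng.random(n) < config.genotype_error_rate
            if err.any():
                which = rng.integers(0, 2, size=int(err.sum()))
                shift = rng.integers(1, 4, size=int(err.sum()))
                idx = np.flatnonzero(err)
                pair[idx, which] = ((pair[idx, which] + shift) % 4).astype(np.int8)
            error_mask[name][chrom] = err
            foreign[name][chrom] = pat
            worker_codes[chrom].append(pair)
    for chrom in queen.chrom_names:
        if worker_names:
            worker_alleles[chrom] = np.stack(worker_codes[chrom], axis=0)
        else:
            worker_alleles[chrom] = np.empty(
                (0, len(queen.positions[chrom]), 2), dtype=np.int8
            )

    events = (
        pd.concat(event_frames, ignore_index=True)
        if event_frames
        else pd.DataFrame(columns=["gamete", "chrom", "kind", "start", "end", "breakpoint"])
    )
    truth = TruthSet(
        events=events,
        cnv_regions=cnv,
        gamete_labels=gamete_labels,
        error_mask=error_mask,
        foreign_haplotypes=foreign,
    )
    return Colony(
        config=config,
        queen=queen,
        drone_names=drone_names,
        worker_names=worker_names,
        drone_alleles=drone_alleles,
        worker_alleles=worker_alleles,
        truth=truth,
    )


def synthesize_reference(
    queen: QueenGenome,
    rng: np.random.Generator,
    gc: float | Mapping[str, np.ndarray] = 0.33,
    gc_window: int = 2000,
) -> dict[str, str]:
    """Random reference sequence consistent with the queen marker map.

    ``gc`` is either a genome-wide GC fraction or a per-chromosome array of
    GC fractions over non-overlapping ``gc_window`` windows (used to plant
    GC landscapes). Haplotype-0 alleles are written at marker positions and
    declared assembly gaps become runs of N.
    """
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out: dict[str, str] = {}
    for name, length in zip(queen.chrom_names, queen.chrom_lengths):
        if isinstance(gc, Mapping):
            win_gc = np.asarray(gc[name], dtype=float)
            per_base = np.repeat(win_gc, gc_window)[:length]
            if len(per_base) < length:
                per_base = np.pad(per_base, (0, length - len(per_base)), constant_values=win_gc[-1])
        else:
            per_base = np.full(length, float(gc))
        u = rng.random(length)
        v = rng.random(length)
        is_gc_base = u < per_base
        # choose within class uniformly: A/T vs C/G
        codes = np.where(is_gc_base, np.where(v < 0.5, 1, 2), np.where(v < 0.5, 0, 3))
        pos = queen.positions[name]
        codes[pos - 1] = queen.alleles[name][:, 0]
        seq = bases[codes].tobytes().decode("ascii")
        arr = bytearray(seq, "ascii")
        for g0, g1 in queen.gaps[name]:
            arr[g0 - 1 : g1] = b"N" * (g1 - g0 + 1)
        out[name] = arr.decode("ascii")
    return out


def simulate_biased_conversions(
    n_tracts: int,
    rng: np.random.Generator,
    gc_bias: float = 0.5,
    tract_mean: float = 700.0,
    marker_spacing: float = 314.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Recipient/donor allele codes for planted conversion tracts.

    Draws ``n_tracts`` geometric tracts, a Poisson number of marker sites
    per tract (tract length over marker spacing), random distinct allele
    pairs per site, and resolves conversion direction: at AT<->GC sites the
    donor is the G/C allele with probability ``gc_bias`` (0.5 = unbiased);
    within-class sites (A/T or G/C pairs) are direction-symmetric. Feed the
    result to :func:`dronemap.landscape.conversion_gc_bias`.
    """
    lengths = rng.geometric(1.0 / tract_mean, size=n_tracts)
    n_sites = rng.poisson(lengths / marker_spacing)
    total = int(n_sites.sum())
    a = rng.integers(0, 4, size=total, dtype=np.int8)
    b = ((a + rng.integers(1, 4, size=total)) % 4).astype(np.int8)
    a_is_at = (a == 0) | (a == 3)
    b_is_at = (b == 0) | (b == 3)
    crossing = a_is_at != b_is_at
    # orient crossing pairs as (at, gc)
    at = np.where(a_is_at, a, b)
    gc = np.where(a_is_at, b, a)
    toward_gc = rng.random(total) < gc_bias
    swap = rng.random(total) < 0.5  # direction of within-class conversions
    recipient = np.where(crossing, np.where(toward_gc, at, gc), np.where(swap, a, b))
    donor = np.where(crossing, np.where(toward_gc, gc, at), np.where(swap, b, a))
    return recipient.astype(np.int8), donor.astype(np.int8)


def reconstruct_drone(colony: Colony, drone: str, chrom: str) -> np.ndarray:
    """Expected drone codes from queen haplotypes + truth labels + CNV + errors.

    Error sites cannot be reproduced deterministically (the flip target was
    random), so they are returned as MISSING and should be excluded when
    checking reconstruction.
    """
    queen = colony.queen
    lab = colony.truth.gamete_labels[drone][chrom]
    pos = queen.positions[chrom]
    codes = queen.alleles[chrom][np.arange(len(pos)), lab].astype(np.int8)
    cnv = colony.truth.cnv_regions
    for _, row in cnv[cnv["chrom"] == chrom].iterrows():
        sel = (pos >= row["start"]) & (pos <= row["end"]) & (lab == row["haplotype"])
        codes[sel] = HET
    codes[colony.truth.error_mask[drone][chrom]] = MISSING
    return codes
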
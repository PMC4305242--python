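"""Recombination event calling: haplotype blocks, CO vs conversion, filters.

Each gamete (a haploid drone, or the queen-derived haplotype resolved from
a diploid worker) is compared marker-by-marker with the queen's two phased
haplotypes, yielding a mosaic of maximal blocks with alternating haplotype
labels. Block *span* is the physical interval between the block's end
markers. Blocks spanning more than ``co_min_span`` (default 10 kb) are the
product of crossovers; interior blocks spanning at most that are gene
conversion tracts. Two adjacent short blocks sitting immediately upstream
of a crossover, with the distal block within ``proximity`` (default 10 kb)
of the crossover block's edge, are the signature of one *complex
CO-associated* conversion; every other short block is a *non-crossover*
(NCO) conversion. Simple CO-associated conversions merge invisibly into
the crossover breakpoint and cannot be recovered from single gametes.

Exclusion filters remove conversion / small-double-crossover candidates
whose switching interval crosses an assembly gap, overlaps a detected
multi-copy region, or fails user-supplied read-evidence predicates
(uninterrupted mapping, normal insert size) mirroring the read-level
checks used on real alignments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._alleles import HET
from .markers import FilteredMarkers
from .phasing import PhasedHaplotypes

__all__ = [
    "segment_blocks",
    "classify_events",
    "associate_conversions",
    "call_drone_events",
    "call_worker_events",
    "call_multicopy_conversions",
    "exclusion_filters",
    "annotate_shared",
    "crossover_rate",
    "rate_excluding",
    "worker_drone_concordance",
    "shared_event_total",
    "conversions_per_gamete",
    "co_associated_fraction",
    "extrapolated_conversions_per_gamete",
]

logger = logging.getLogger(__name__)

BLOCK_COLUMNS = [
    "gamete", "chrom", "label", "first_pos", "last_pos", "n_markers",
    "span", "flank_left", "flank_right", "terminal",
]
EVENT_COLUMNS = [
    "gamete", "chrom", "kind", "start", "end", "midpoint",
    "n_markers", "span", "flank_left", "flank_right",
]


def _smooth_singletons(labels: np.ndarray, tolerance: int) -> np.ndarray:
    """Reassign isolated discordant sites flanked by >=tolerance consistent ones.

    A run of length 1 whose two neighbouring runs each hold at least
    ``tolerance`` markers is treated as a genotyping error and relabeled to
    its flanks (which, labels being binary, necessarily agree). With
    ``tolerance=0`` nothing is smoothed and single-marker conversion
    tracts are kept.
    """
    if tolerance <= 0 or len(labels) < 3:
        return labels
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        boundaries = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(labels)]])
        lengths = ends - starts
        for k in range(1, len(starts) - 1):
            if (
                lengths[k] == 1
                and lengths[k - 1] >= tolerance
                and lengths[k + 1] >= tolerance
            ):
                labels[starts[k]] = labels[starts[k - 1]]
                changed = True
    return labels


def segment_blocks(
    positions: np.ndarray,
    phased: PhasedHaplotypes,
    gamete_codes: np.ndarray,
    gamete: str = "g0",
    error_tolerance: int = 2,
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Segment one gamete chromosome into maximal haplotype blocks.

    Sites whose call matches neither phased haplotype (errors, het calls,
    missing) are skipped. Returns a block table (one row per maximal run)
    or an empty frame if the gamete is unusable at this chromosome.
    """
    label = np.full(len(positions), -1, dtype=np.int8)
    label[gamete_codes == phased.hap0] = 0
    label[gamete_codes == phased.hap1] = 1
    usable = label >= 0
    if len(positions) and usable.mean() < (1 - max_missing_fraction):
        warnings.warn(
            f"{gamete}/{phased.chrom}: >{max_missing_fraction:.0%} of markers "
            "unusable; gamete excluded on this chromosome",
            stacklevel=2,
        )
        return pd.DataFrame(columns=BLOCK_COLUMNS)
    pos = positions[usable]
    lab = _smooth_singletons(label[usable], error_tolerance)
    if len(pos) == 0:
        return pd.DataFrame(columns=BLOCK_COLUMNS)
    boundaries = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries - 1, [len(lab) - 1]])
    rows = []
    for s, e in zip(starts, ends):
        rows.append(
            (
                gamete,
                phased.chrom,
                int(lab[s]),
                int(pos[s]),
                int(pos[e]),
                int(e - s + 1),
                int(pos[e] - pos[s]),
                int(pos[s - 1]) if s > 0 else -1,
                int(pos[e + 1]) if e + 1 < len(pos) else -1,
                s == 0 or e == len(lab) - 1,
            )
        )
    return pd.DataFrame(rows, columns=BLOCK_COLUMNS)


def classify_events(blocks: pd.DataFrame, co_min_span: int = 10_000) -> pd.DataFrame:
    """Classify the block mosaic into crossovers and conversion candidates.

    Within each gamete x chromosome, blocks spanning more than
    ``co_min_span`` anchor the chromosome backbone; every transition
    between consecutive anchors is one crossover, whose breakpoint interval
    runs from the last marker before the switch to the first marker after
    it. Interior short blocks become conversion candidates (kind
    ``NCO_conversion`` until :func:`associate_conversions` refines them).
    Terminal blocks generate no event.
    """
    out: list[tuple] = []
    if len(blocks) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    for (gamete, chrom), grp in blocks.groupby(["gamete", "chrom"], sort=False):
        grp = grp.reset_index(drop=True)
        long = (grp["span"] > co_min_span).to_numpy()
        anchors = np.flatnonzero(long)
        # conversion candidates: interior short blocks
        for i in np.flatnonzero(~long):
            row = grp.iloc[i]
            if row["terminal"]:
                continue
            out.append(
                (
                    gamete, chrom, "NCO_conversion",
                    int(row["first_pos"]), int(row["last_pos"]),
                    0.5 * (row["first_pos"] + row["last_pos"]),
                    int(row["n_markers"]), int(row["span"]),
                    int(row["flank_left"]), int(row["flank_right"]),
                )
            )
        # crossovers: one per consecutive-anchor pair with a net label change
        for a, b in zip(anchors[:-1], anchors[1:]):
            la, lb = grp.loc[a, "label"], grp.loc[b, "label"]
            if la == lb:
                continue  # even number of tract flips in between, no net CO
            # breakpoint interval: between the last short block (or anchor a)
            # and anchor b
            left = int(grp.loc[b - 1, "last_pos"])
            right = int(grp.loc[b, "first_pos"])
            out.append(
                (
                    gamete, chrom, "CO", left, right, 0.5 * (left + right),
                    0, right - left, left, right,
                )
            )
    return pd.DataFrame(out, columns=EVENT_COLUMNS).sort_values(
        ["gamete", "chrom", "start"], ignore_index=True
    )


def associate_conversions(
    events: pd.DataFrame,
    blocks: pd.DataFrame,
    co_min_span: int = 10_000,
    proximity: int = 10_000,
) -> pd.DataFrame:
    """Promote the interleaved double-short-block pattern to CO_conversion.

    Two conversion candidates in adjacent blocks, sitting immediately
    against a crossover block, are one complex CO-associated conversion
    when the distal block starts within ``proximity`` of the crossover
    block's edge. The pair is merged into a single ``CO_conversion`` event
    spanning both tracts; everything else stays ``NCO_conversion``.
    """
    if len(events) == 0:
        return events.copy()
    events = events.copy()
    drop: list[int] = []
    for (gamete, chrom), grp in blocks.groupby(["gamete", "chrom"], sort=False):
        grp = grp.reset_index(drop=True)
        long = (grp["span"] > co_min_span).to_numpy()
        n = len(grp)
        # scan for runs of exactly >=2 consecutive shorts bounded by anchors
        i = 0
        while i < n:
            if long[i] or grp.loc[i, "terminal"]:
                i += 1
                continue
            j = i
            while j + 1 < n and not long[j + 1] and not grp.loc[j + 1, "terminal"]:
                j += 1
            # shorts i..j, bounded by anchors i-1 and j+1 when they exist
            left_anchor = i - 1 if i - 1 >= 0 and long[i - 1] else None
            right_anchor = j + 1 if j + 1 < n and long[j + 1] else None
            if (
                j > i
                and left_anchor is not None
                and right_anchor is not None
                and grp.loc[left_anchor, "label"] != grp.loc[right_anchor, "label"]
            ):
                # net switch: the two shorts nearest the downstream anchor
                distal, proximal = j - 1, j
                dist = grp.loc[right_anchor, "first_pos"] - grp.loc[distal, "first_pos"]
                if dist <= proximity:
                    sel = events.index[
                        (events["gamete"] == gamete)
                        & (events["chrom"] == chrom)
                        & (events["kind"] == "NCO_conversion")
                        & events["start"].isin(
                            [grp.loc[distal, "first_pos"], grp.loc[proximal, "first_pos"]]
                        )
                    ]
                    if len(sel) == 2:
                        first, second = sel
                        events.loc[first, ["kind", "end", "midpoint", "n_markers", "span", "flank_right"]] = [
                            "CO_conversion",
                            int(grp.loc[proximal, "last_pos"]),
                            0.5 * (grp.loc[distal, "first_pos"] + grp.loc[proximal, "last_pos"]),
                            int(grp.loc[distal, "n_markers"] + grp.loc[proximal, "n_markers"]),
                            int(grp.loc[proximal, "last_pos"] - grp.loc[distal, "first_pos"]),
                            int(grp.loc[proximal, "flank_right"]),
                        ]
                        drop.append(second)
            i = j + 1
    return events.drop(index=drop).reset_index(drop=True)


def call_drone_events(
    markers: FilteredMarkers,
    phased: Mapping[str, PhasedHaplotypes],
    co_min_span: int = 10_000,
    proximity: int = 10_000,
    error_tolerance: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and classify every drone; returns (events, blocks)."""
    all_blocks = []
    for d, name in enumerate(_drone_names(markers)):
        for chrom in markers.chrom_names:
            all_blocks.append(
                segment_blocks(
                    markers.positions[chrom],
                    phased[chrom],
                    markers.drone_alleles[chrom][d],
                    gamete=name,
                    error_tolerance=error_tolerance,
                )
            )
    blocks = pd.concat(all_blocks, ignore_index=True)
    events = classify_events(blocks, co_min_span)
    events = associate_conversions(events, blocks, co_min_span, proximity)
    return events, blocks


def _drone_names(markers: FilteredMarkers) -> list[str]:
    n = next(iter(markers.drone_alleles.values())).shape[0]
    return [f"drone{i + 1}" for i in range(n)]


def resolve_worker_haplotype(
    alleles: np.ndarray, worker_pairs: np.ndarray
) -> np.ndarray:
    """Queen-derived allele per marker site for one worker chromosome.

    ``worker_pairs`` is (n_sites, 2) of observed codes. A homozygous call
    fixes the queen allele; a het call sharing exactly one allele with the
    queen pair fixes it too; a het call equal to the queen's own pair is
    unresolvable (-1).
    """
    x, y = worker_pairs[:, 0], worker_pairs[:, 1]
    a, b = alleles[:, 0], alleles[:, 1]
    out = np.full(len(x), -1, dtype=np.int8)
    hom = x == y
    out[hom & ((x == a) | (x == b))] = x[hom & ((x == a) | (x == b))]
    het = ~hom
    x_in = (x == a) | (x == b)
    y_in = (y == a) | (y == b)
    only_x = het & x_in & ~y_in
    only_y = het & y_in & ~x_in
    out[only_x] = x[only_x]
    out[only_y] = y[only_y]
    return out


def call_worker_events(
    markers: FilteredMarkers,
    phased: Mapping[str, PhasedHaplotypes],
    co_min_span: int = 10_000,
    error_tolerance: int = 2,
    min_resolvable_fraction: float = 0.10,
    max_missing_fraction: float = 0.85,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crossovers on the queen-derived haplotype of each diploid worker.

    Unresolvable sites (worker het equal to the queen's allele pair) are
    dropped before segmentation; conversions are never emitted for workers
    because het-to-hom miscalls mimic short tracts. Workers resolving fewer
    than ``min_resolvable_fraction`` of sites are excluded. Returns
    (events restricted to COs, per-worker summary).
    """
    all_blocks = []
    summaries = []
    n_workers = next(iter(markers.worker_alleles.values())).shape[0]
    for w in range(n_workers):
        name = f"worker{w + 1}"
        n_res = n_tot = 0
        per_chrom = []
        for chrom in markers.chrom_names:
            resolved = resolve_worker_haplotype(
                markers.alleles[chrom], markers.worker_alleles[chrom][w]
            )
            n_res += int((resolved >= 0).sum())
            n_tot += len(resolved)
            per_chrom.append((chrom, resolved))
        frac = n_res / max(n_tot, 1)
        summaries.append((name, n_tot, n_res, frac))
        if frac < min_resolvable_fraction:
            warnings.warn(f"{name}: only {frac:.1%} of sites resolvable; excluded")
            continue
        for chrom, resolved in per_chrom:
            all_blocks.append(
                segment_blocks(
                    markers.positions[chrom],
                    phased[chrom],
                    resolved,
                    gamete=name,
                    error_tolerance=error_tolerance,
                    # roughly half of all sites are unresolvable by design
                    # (worker het equal to the queen's pair), so the drone
                    # missingness guard does not apply
                    max_missing_fraction=max_missing_fraction,
                )
            )
    blocks = (
        pd.concat(all_blocks, ignore_index=True)
        if all_blocks
        else pd.DataFrame(columns=BLOCK_COLUMNS)
    )
    events = classify_events(blocks, co_min_span)
    events = events[events["kind"] == "CO"].reset_index(drop=True)
    summary = pd.DataFrame(
        summaries, columns=["gamete", "n_sites", "n_resolved", "resolved_fraction"]
    )
    return events, summary


def call_multicopy_conversions(
    colony_drone_alleles: Mapping[str, np.ndarray],
    positions: Mapping[str, np.ndarray],
    regions: pd.DataFrame,
    min_sites: int = 2,
    coverage_ok: Mapping[tuple[str, int], bool] | None = None,
    drone_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene-conversion candidates inside multi-copy regions.

    A region is informative when its member sites show two discriminable
    drone patterns (some drones constantly heterozygous -- they inherited
    the duplication-bearing haplotype -- and some constantly homozygous). A
    drone whose pattern switches het<->hom across >=``min_sites``
    consecutive member sites, without coverage-drop evidence, is one
    conversion candidate. ``coverage_ok`` maps (chrom, region index) ->
    bool; missing entries default to True.
    """
    rows = []
    for r, reg in regions.iterrows():
        chrom = reg["chrom"]
        pos = positions[chrom]
        member = np.flatnonzero((pos >= reg["start"]) & (pos <= reg["end"]))
        if len(member) < min_sites:
            continue
        codes = colony_drone_alleles[chrom][:, member]
        het = codes == HET
        hom = codes >= 0
        state = np.where(het, 1, np.where(hom, 0, -1))
        informative = state >= 0
        const_het = ((state == 1) | ~informative).all(axis=1) & het.any(axis=1)
        const_hom = ((state == 0) | ~informative).all(axis=1) & hom.any(axis=1)
        if not (const_het.any() and const_hom.any()):
            continue  # no two discriminable haplotype patterns
        if coverage_ok is not None and not coverage_ok.get((chrom, r), True):
            continue
        n_drones = codes.shape[0]
        names = drone_names or [f"drone{i + 1}" for i in range(n_drones)]
        for d in range(n_drones):
            s = state[d][informative[d]]
            p = pos[member][informative[d]]
            if len(s) < 2 * min_sites or (s == s[0]).all():
                continue
            boundaries = np.flatnonzero(np.diff(s)) + 1
            if len(boundaries) > 2:
                continue  # more than one switch: unreliable pattern
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(s)]])
            lengths = ends - starts
            # baseline = the flanking/majority state; switched = the minority
            # run (ties resolve to the later run, i.e. the change)
            k = len(lengths) - 1 - int(np.argmin(lengths[::-1]))
            if lengths[k] < min_sites or lengths.max() < min_sites:
                continue
            rows.append(
                (
                    names[d], chrom, "multicopy_conversion",
                    int(p[starts[k]]), int(p[ends[k] - 1]),
                    0.5 * (p[starts[k]] + p[ends[k] - 1]),
                    int(lengths[k]), int(p[ends[k] - 1] - p[starts[k]]),
                    int(reg["start"]), int(reg["end"]),
                )
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# exclusion filters


def exclusion_filters(
    events: pd.DataFrame,
    gaps: Mapping[str, np.ndarray] | None = None,
    multicopy: pd.DataFrame | None = None,
    paralog_ambiguous: Callable[[pd.Series], bool] | None = None,
    read_uninterrupted: Callable[[pd.Series], bool] | None = None,
    insert_size_normal: Callable[[pd.Series], bool] | None = None,
    double_co_max_run: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove candidates explicable by non-allelic alignment artifacts.

    Four checks, applied to conversions and to crossovers bounding a short
    (< ``double_co_max_run``) double-crossover block: (1) an assembly gap
    inside the switching interval; (2) a user paralog-ambiguity predicate;
    (3)/(4) read-evidence predicates (uninterrupted mapping, normal insert
    size) -- skipped with a logged notice when not supplied. Events
    overlapping a detected multi-copy region are removed unconditionally.
    Returns (kept, removed-with-reason).
    """
    events = events.reset_index(drop=True)
    reason = pd.Series("", index=events.index, dtype=object)

    is_conv = events["kind"].str.contains("conversion")
    small_double = _double_co_mask(events, double_co_max_run)
    checkable = is_conv | small_double

    if gaps:
        for i in events.index[checkable]:
            ev = events.loc[i]
            g = np.asarray(gaps.get(ev["chrom"], ())).reshape(-1, 2)
            left = ev["flank_left"] if ev["flank_left"] >= 0 else ev["start"]
            right = ev["flank_right"] if ev["flank_right"] >= 0 else ev["end"]
            if len(g) and ((g[:, 0] <= right) & (g[:, 1] >= left)).any():
                reason.loc[i] = "gap"
    if multicopy is not None and len(multicopy):
        # the mask targets conversion-sized candidates: an isolated crossover
        # spanning a masked region is still a clean switch between the
        # flanking retained markers
        for i in events.index[checkable & (reason == "")]:
            ev = events.loc[i]
            m = multicopy[multicopy["chrom"] == ev["chrom"]]
            if len(m) and ((m["start"] <= ev["end"]) & (m["end"] >= ev["start"])).any():
                reason.loc[i] = "cnv_mask"
    for name, predicate in (
        ("paralog", paralog_ambiguous),
        ("read_interrupted", read_uninterrupted),
        ("insert_size", insert_size_normal),
    ):
        if predicate is None:
            if name != "paralog":
                logger.info("read-evidence filter %r skipped: no evidence supplied", name)
            continue
        for i in events.index[checkable & (reason == "")]:
            ok = predicate(events.loc[i])
            if (name == "paralog" and ok) or (name != "paralog" and not ok):
                reason.loc[i] = name

    removed = events[reason != ""].copy()
    removed["reason"] = reason[reason != ""]
    kept = events[reason == ""].reset_index(drop=True)
    return kept, removed.reset_index(drop=True)


def _double_co_mask(events: pd.DataFrame, max_run: int) -> pd.Series:
    """Crossovers bounding an inter-crossover block shorter than max_run."""
    mask = pd.Series(False, index=events.index)
    co = events[events["kind"] == "CO"]
    for (_, _), grp in co.groupby(["gamete", "chrom"], sort=False):
        grp = grp.sort_values("midpoint")
        idx = grp.index.to_numpy()
        mids = grp["midpoint"].to_numpy()
        close = np.diff(mids) < max_run
        for k in np.flatnonzero(close):
            mask.loc[idx[k]] = True
            mask.loc[idx[k + 1]] = True
    return mask


def annotate_shared(events: pd.DataFrame) -> pd.DataFrame:
    """Group crossovers shared across gametes by overlapping intervals.

    Crossovers in different gametes are "the same" event when their
    flanking-marker intervals overlap (transitively chained). Adds
    ``shared_count`` (gametes per group) and ``shared_group`` columns.
    """
    events = events.copy()
    events["shared_count"] = 1
    events["shared_group"] = -1
    co = events[events["kind"] == "CO"]
    gid = 0
    for chrom, grp in co.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        idx = grp.index.to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur: list[int] = []
        max_end = -1
        for k in range(len(idx)):
            if cur and starts[k] > max_end:
                _assign_group(events, cur, gid)
                gid += 1
                cur = []
                max_end = -1
            cur.append(idx[k])
            max_end = max(max_end, ends[k])
        if cur:
            _assign_group(events, cur, gid)
            gid += 1
    return events


def _assign_group(events: pd.DataFrame, members: list[int], gid: int) -> None:
    gametes = events.loc[members, "gamete"].nunique()
    events.loc[members, "shared_group"] = gid
    events.loc[members, "shared_count"] = gametes


def conversion_site_alleles(
    markers: FilteredMarkers,
    events: pd.DataFrame,
    kinds: Sequence[str] = ("NCO_conversion",),
) -> tuple[np.ndarray, np.ndarray]:
    """Recipient/donor allele codes at every converted marker site.

    For each conversion tract the *donor* allele at a member site is the
    one the gamete actually shows (copied in from the other haplotype) and
    the *recipient* allele is the one it overwrote. Used by the u/v
    GC-bias statistic. Gamete names must index into the drone matrix
    ("drone1", ...).
    """
    rec: list[int] = []
    don: list[int] = []
    conv = events[events["kind"].isin(kinds)]
    for _, evr in conv.iterrows():
        chrom = evr["chrom"]
        d = int(str(evr["gamete"]).removeprefix("drone")) - 1
        pos = markers.positions[chrom]
        sel = (pos >= evr["start"]) & (pos <= evr["end"])
        codes = markers.drone_alleles[chrom][d, sel]
        alleles = markers.alleles[chrom][sel]
        for c, (a, b) in zip(codes, alleles):
            if c == a:
                don.append(int(a)); rec.append(int(b))
            elif c == b:
                don.append(int(b)); rec.append(int(a))
    return np.array(rec, dtype=np.int8), np.array(don, dtype=np.int8)


# ---------------------------------------------------------------------------
# rates and worked-example arithmetic


def crossover_rate(total_cos: float, genome_mb: float, n_gametes: int) -> float:
    """Recombination rate in cM/Mb: 100 x (COs per gamete) / Mb."""
    if n_gametes < 1:
        raise ValueError("need at least one gamete")
    if genome_mb <= 0:
        raise ValueError("genome size must be positive")
    return 100.0 * (total_cos / n_gametes) / genome_mb


def rate_excluding(
    events: pd.DataFrame,
    genome_mb: float,
    n_gametes: int,
    mode: str,
    gaps: Mapping[str, np.ndarray] | None = None,
    shared_min: int = 5,
) -> float:
    """Sensitivity-analysis rate recomputations.

    ``mode="drop_multi_co_gap"`` removes every crossover whose
    flanking-marker interval hosts more than one crossover (across
    gametes) and subtracts the gap length annotated inside those intervals
    from the genome size. ``mode="drop_shared"`` removes crossovers shared
    by >= ``shared_min`` gametes.
    """
    co = annotate_shared(events)
    co = co[co["kind"] == "CO"]
    if mode == "drop_shared":
        kept = co[co["shared_count"] < shared_min]
        return crossover_rate(len(kept), genome_mb, n_gametes)
    if mode == "drop_multi_co_gap":
        sizes = co.groupby("shared_group")["gamete"].size()
        multi = set(sizes.index[sizes > 1])
        kept = co[~co["shared_group"].isin(multi)]
        removed = co[co["shared_group"].isin(multi)]
        gap_bp = 0
        if gaps:
            for _, grp in removed.groupby("shared_group"):
                chrom = grp["chrom"].iloc[0]
                g = np.asarray(gaps.get(chrom, ())).reshape(-1, 2)
                lo, hi = grp["start"].min(), grp["end"].max()
                for g0, g1 in g:
                    if g0 <= hi and g1 >= lo:
                        gap_bp += g1 - g0 + 1
        return crossover_rate(len(kept), genome_mb - gap_bp / 1e6, n_gametes)
    raise ValueError(f"unknown mode {mode!r}")


def worker_drone_concordance(
    drone_counts: Sequence[float],
    worker_counts: Sequence[float],
    method: str = "brunner-munzel",
) -> tuple[float, float]:
    """Two-sided test that worker and drone crossover counts agree.

    ``method`` is "brunner-munzel" or "mann-whitney" (exact rank test; the
    better-calibrated choice below ~10 samples per group). Returns
    (statistic, p-value).
    """
    if method == "brunner-munzel":
        res = stats.brunnermunzel(drone_counts, worker_counts)
    elif method == "mann-whitney":
        res = stats.mannwhitneyu(drone_counts, worker_counts, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def shared_event_total(multiplicity: Mapping[int, int]) -> int:
    """Total crossovers inside shared groups: sum of k x n_k over k >= 2."""
    return int(sum(k * n for k, n in multiplicity.items() if k >= 2))


def conversions_per_gamete(
    n_standard: int, n_multicopy: int, n_gametes: int
) -> float:
    """Observed conversions per meiosis, multi-copy candidates included."""
    return (n_standard + n_multicopy) / n_gametes


def co_associated_fraction(n_associated: int, n_co: int) -> float:
    """Fraction of crossovers with a discernible associated conversion."""
    return n_associated / n_co


def extrapolated_conversions_per_gamete(
    n_complex: int, complex_fraction: float, n_nco: int, n_gametes: int
) -> float:
    """Conversions per meiosis if only ``complex_fraction`` of CO-associated
    tracts are discernible in haploid gametes (the rest merge into the
    crossover): (n_complex / complex_fraction + n_nco) / n_gametes."""
    if not 0 < complex_fraction <= 1:
        raise ValueError("complex_fraction must be in (0, 1]")
    return (n_complex / complex_fraction + n_nco) / n_gametes
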
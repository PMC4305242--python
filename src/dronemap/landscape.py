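"""Genome-landscape statistics of the recombination map.

Windowed crossover rates (cM/Mb), Poisson hot/cold windows and merged
hot/cold regions, GC content around breakpoints against a positional
randomization null, GC-vs-rate correlation with 1%-GC-bin smoothing,
covariate correlations across window scales, motif shuffle enrichment,
the u/v statistic of GC-biased gene conversion, marker-downsampling
curves, and gene-set proximity enrichment (2x2 chi-square).

Windows are half-open ``[start, end)`` in 0-based coordinates internally;
exported tables convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._alleles import encode_sequence, is_gc

__all__ = [
    "make_windows",
    "window_rates",
    "annotate_windows",
    "hotspot_test",
    "merge_regions",
    "gc_breakpoint_profile",
    "gc_rate_relation",
    "covariate_correlations",
    "motif_shuffle_test",
    "conversion_gc_bias",
    "marker_downsampling",
    "proximity_enrichment",
    "enrichment_from_counts",
    "EnrichmentResult",
]


def make_windows(chrom_lengths: Mapping[str, int], size: int) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows of ``size`` bp."""
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, size, dtype=np.int64)
        ends = np.minimum(starts + size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def window_rates(
    events: pd.DataFrame, windows: pd.DataFrame, n_gametes: int
) -> pd.DataFrame:
    """Crossover count and cM/Mb per window (events assigned by midpoint)."""
    windows = windows.copy()
    windows["co_count"] = 0
    co = events[events["kind"] == "CO"]
    for chrom, grp in co.groupby("chrom", sort=False):
        sel = windows["chrom"] == chrom
        if not sel.any():
            continue
        starts = windows.loc[sel, "start"].to_numpy()
        # midpoints are 1-based bp; windows 0-based half-open
        mids = grp["midpoint"].to_numpy() - 1
        idx = np.searchsorted(starts, mids, side="right") - 1
        counts = np.bincount(idx[idx >= 0], minlength=sel.sum())
        windows.loc[sel, "co_count"] = counts
    span_mb = (windows["end"] - windows["start"]) / 1e6
    windows["rate"] = 100.0 * (windows["co_count"] / n_gametes) / span_mb
    return windows


def annotate_windows(
    windows: pd.DataFrame,
    reference: Mapping[str, str] | None = None,
    marker_positions: Mapping[str, np.ndarray] | None = None,
    genes: pd.DataFrame | None = None,
    multicopy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Add gc, n_fraction, diversity (marker density), gene_count, cnv_bp."""
    windows = windows.copy()
    if reference is not None:
        gc = np.zeros(len(windows))
        nf = np.zeros(len(windows))
        for chrom, seq in reference.items():
            sel = windows.index[windows["chrom"] == chrom]
            if len(sel) == 0:
                continue
            codes = encode_sequence(seq)
            cg = np.concatenate([[0], np.cumsum(is_gc(codes).astype(np.int64))])
            cn = np.concatenate([[0], np.cumsum((codes < 0).astype(np.int64))])
            s = windows.loc[sel, "start"].to_numpy()
            e = windows.loc[sel, "end"].to_numpy()
            n_bases = cn[e] - cn[s]
            valid = (e - s) - n_bases
            with np.errstate(invalid="ignore", divide="ignore"):
                gc[sel] = np.where(valid > 0, (cg[e] - cg[s]) / np.maximum(valid, 1), np.nan)
            nf[sel] = n_bases / (e - s)
        windows["gc"] = gc
        windows["n_fraction"] = nf
    if marker_positions is not None:
        div = np.zeros(len(windows))
        for chrom, pos in marker_positions.items():
            sel = windows.index[windows["chrom"] == chrom]
            if len(sel) == 0:
                continue
            s = windows.loc[sel, "start"].to_numpy()
            e = windows.loc[sel, "end"].to_numpy()
            counts = np.searchsorted(pos - 1, e) - np.searchsorted(pos - 1, s)
            div[sel] = counts / (e - s)
        windows["diversity"] = div
    if genes is not None:
        windows["gene_count"] = _interval_counts(windows, genes)
    if multicopy is not None:
        windows["cnv_bp"] = _interval_overlap_bp(windows, multicopy)
    return windows


def _interval_counts(windows: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Number of intervals whose midpoint falls in each window."""
    out = np.zeros(len(windows), dtype=np.int64)
    for chrom, grp in intervals.groupby("chrom", sort=False):
        sel = windows.index[windows["chrom"] == chrom]
        if len(sel) == 0:
            continue
        starts = windows.loc[sel, "start"].to_numpy()
        mids = (grp["start"].to_numpy() + grp["end"].to_numpy()) / 2 - 1
        idx = np.searchsorted(starts, mids, side="right") - 1
        out[sel] += np.bincount(idx[idx >= 0], minlength=len(sel))
    return out


def _interval_overlap_bp(windows: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    out = np.zeros(len(windows), dtype=np.int64)
    for chrom, grp in intervals.groupby("chrom", sort=False):
        sel = windows.index[windows["chrom"] == chrom]
        if len(sel) == 0:
            continue
        ws = windows.loc[sel, "start"].to_numpy()
        we = windows.loc[sel, "end"].to_numpy()
        for s, e in zip(grp["start"].to_numpy() - 1, grp["end"].to_numpy()):
            out[sel] += np.clip(np.minimum(we, e) - np.maximum(ws, s), 0, None)
    return out


def hotspot_test(windows: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-window Poisson hot/cold tests against the genome-mean rate.

    The null mean for window i is the genome-wide crossover density per bp
    times the window length, so partial chromosome-end windows are not
    spuriously cold. Emits raw one-tailed p-values (hot: P(X >= k); cold:
    P(X <= k)) and Benjamini-Hochberg adjusted calls at ``alpha``.
    """
    windows = windows.copy()
    total_bp = (windows["end"] - windows["start"]).sum()
    dens = windows["co_count"].sum() / total_bp
    lam = dens * (windows["end"] - windows["start"])
    k = windows["co_count"].to_numpy()
    windows["lambda"] = lam
    windows["p_hot"] = stats.poisson.sf(k - 1, lam)
    windows["p_cold"] = stats.poisson.cdf(k, lam)
    windows["hot_raw"] = windows["p_hot"] < alpha
    windows["cold_raw"] = windows["p_cold"] < alpha
    for side in ("hot", "cold"):
        adj = multipletests(windows[f"p_{side}"], alpha=alpha, method="fdr_bh")[0]
        windows[f"{side}_bh"] = adj
    return windows


def merge_regions(windows: pd.DataFrame, which: str = "hot_raw") -> pd.DataFrame:
    """Merge runs of adjacent significant windows into regions (BED-like)."""
    sig = windows[windows[which]].sort_values(["chrom", "start"])
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        cur_s = cur_e = None
        for _, row in grp.iterrows():
            if cur_e is not None and row["start"] <= cur_e:
                cur_e = max(cur_e, row["end"])
            else:
                if cur_s is not None:
                    rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = row["start"], row["end"]
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# GC statistics


def _gc_cumsums(reference: Mapping[str, str]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, seq in reference.items():
        codes = encode_sequence(seq)
        cg = np.concatenate([[0], np.cumsum(is_gc(codes).astype(np.int64))])
        cn = np.concatenate([[0], np.cumsum((codes < 0).astype(np.int64))])
        out[chrom] = (cg, cn)
    return out


def _window_gc(
    cums: Mapping[str, tuple[np.ndarray, np.ndarray]],
    chrom: np.ndarray,
    centers: np.ndarray,
    window: int,
    offsets: np.ndarray,
) -> np.ndarray:
    """GC per (breakpoint, relative window); NaN for off-chromosome or all-N."""
    out = np.full((len(centers), len(offsets)), np.nan)
    half = window // 2
    for c in np.unique(chrom):
        cg, cn = cums[c]
        length = len(cg) - 1
        sel = np.flatnonzero(chrom == c)
        ctr = centers[sel].astype(np.int64)
        for j, off in enumerate(offsets):
            s = ctr + off * window - half
            e = s + window
            ok = (s >= 0) & (e <= length)
            si, ei = s[ok], e[ok]
            n_bases = cn[ei] - cn[si]
            valid = (ei - si) - n_bases
            gc = np.where(valid > 0, (cg[ei] - cg[si]) / np.maximum(valid, 1), np.nan)
            out[sel[ok], j] = gc
    return out


def gc_breakpoint_profile(
    reference: Mapping[str, str],
    breakpoints: pd.DataFrame,
    window: int = 2000,
    flank_windows: int = 5,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
    batch: int = 200,
) -> tuple[pd.DataFrame, float]:
    """Mean GC in 2 kb windows around breakpoints, with a randomization p.

    The observed profile averages GC over ``2*flank_windows + 1`` windows
    centred on each crossover breakpoint midpoint (all-N and
    off-chromosome windows are excluded from the average). The null draws
    the same number of positions uniformly from the non-N genome ``reps``
    times; the empirical p is (M+1)/(reps+1) where M counts null central
    windows with mean GC at least the observed (one-sided enrichment).
    """
    rng = np.random.default_rng() if rng is None else rng
    cums = _gc_cumsums(reference)
    offsets = np.arange(-flank_windows, flank_windows + 1)
    chrom = breakpoints["chrom"].to_numpy()
    centers = breakpoints["midpoint"].to_numpy().astype(np.int64) - 1
    obs = _window_gc(cums, chrom, centers, window, offsets)
    profile = pd.DataFrame(
        {
            "offset": offsets,
            "gc": np.nanmean(obs, axis=0),
            "n": np.sum(~np.isnan(obs), axis=0),
        }
    )
    obs_central = float(np.nanmean(obs[:, flank_windows]))

    # null frame: non-N positions at least half a window from chromosome
    # edges, over a concatenated genome so sampling is fully vectorized
    half = window // 2
    offs: list[int] = []
    cat_gc: list[np.ndarray] = []
    cat_n: list[np.ndarray] = []
    frame_parts: list[np.ndarray] = []
    offset = 0
    for c, seq in reference.items():
        codes = encode_sequence(seq)
        cat_gc.append(is_gc(codes).astype(np.int64))
        cat_n.append((codes < 0).astype(np.int64))
        good = np.flatnonzero(codes >= 0)
        good = good[(good >= half) & (good + window - half <= len(codes))]
        frame_parts.append(good + offset)
        offs.append(offset)
        offset += len(codes)
    cg_all = np.concatenate([[0], np.cumsum(np.concatenate(cat_gc))])
    cn_all = np.concatenate([[0], np.cumsum(np.concatenate(cat_n))])
    frame = np.concatenate(frame_parts)
    n_bp = len(centers)

    m = 0
    for start in range(0, reps, batch):
        b = min(batch, reps - start)
        pos = frame[rng.integers(0, len(frame), size=(b, n_bp))]
        s = pos - half
        e = s + window
        n_bases = cn_all[e] - cn_all[s]
        valid = window - n_bases
        with np.errstate(invalid="ignore", divide="ignore"):
            gc = np.where(valid > 0, (cg_all[e] - cg_all[s]) / np.maximum(valid, 1), np.nan)
        null_means = np.nanmean(gc, axis=1)
        m += int((null_means >= obs_central).sum())
    p = (m + 1) / (reps + 1)
    return profile, float(p)


def gc_rate_relation(
    windows: pd.DataFrame,
    bin_width: float = 0.01,
    min_windows_per_bin: int = 100,
    max_n_fraction: float = 0.10,
) -> tuple[float, float, pd.DataFrame]:
    """Spearman GC-vs-rate correlation plus the 1%-GC-bin smoothed curve.

    Windows with more than ``max_n_fraction`` N are excluded from the
    binned curve, and so are GC bins holding fewer than
    ``min_windows_per_bin`` windows. Returns (rho, p, bin table with
    mean rate and s.e.m. plus the fitted cM/Mb-per-%GC slope as attrs).
    """
    ok = windows.dropna(subset=["gc", "rate"])
    rho, p = stats.spearmanr(ok["gc"], ok["rate"])
    binned = ok[ok["n_fraction"] <= max_n_fraction] if "n_fraction" in ok else ok
    bins = (binned["gc"] / bin_width).astype(int)
    table = (
        binned.assign(gc_bin=bins * bin_width)
        .groupby("gc_bin")["rate"]
        .agg(["mean", "sem", "size"])
        .reset_index()
        .rename(columns={"mean": "rate_mean", "sem": "rate_sem", "size": "n_windows"})
    )
    table = table[table["n_windows"] >= min_windows_per_bin].reset_index(drop=True)
    if len(table) >= 2:
        slope = stats.linregress(table["gc_bin"] * 100, table["rate_mean"]).slope
        table.attrs["rate_per_gc_percent"] = float(slope)
        table.attrs["gc_percent_per_rate"] = float(1.0 / slope) if slope else np.nan
    return float(rho), float(p), table


def covariate_correlations(
    windows_by_scale: Mapping[int, pd.DataFrame],
    covariates: Sequence[str] = ("diversity", "gene_count", "cnv_bp"),
) -> pd.DataFrame:
    """Spearman rho of rate vs each covariate at each window scale."""
    rows = []
    for scale, wdf in windows_by_scale.items():
        for cov in covariates:
            if cov not in wdf:
                continue
            ok = wdf.dropna(subset=[cov, "rate"])
            rho, p = stats.spearmanr(ok[cov], ok["rate"])
            rows.append((scale, cov, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["scale", "covariate", "rho", "p"])


# ---------------------------------------------------------------------------
# motif shuffling


def _count_motif(seq_codes: np.ndarray, motif_codes: np.ndarray) -> int:
    """Overlapping occurrences of a motif in an encoded sequence."""
    k = len(motif_codes)
    if len(seq_codes) < k:
        return 0
    view = np.lib.stride_tricks.sliding_window_view(seq_codes, k)
    return int((view == motif_codes).all(axis=1).sum())


def _kmer_counts(seq_codes: np.ndarray, k: int) -> np.ndarray:
    """Counts of every k-mer (4^k table); windows containing N excluded."""
    n = len(seq_codes)
    if n < k:
        return np.zeros(4**k, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    view = np.lib.stride_tricks.sliding_window_view(seq_codes, k)
    ok = (view >= 0).all(axis=1)
    ids = (view[ok].astype(np.int64) * powers).sum(axis=1)
    return np.bincount(ids, minlength=4**k)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(codes.dtype)


def motif_shuffle_test(
    motif: str,
    sequences: Sequence[str],
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
    both_strands: bool = True,
) -> tuple[int, float]:
    """Is a motif more frequent than shuffled versions of itself?

    Counts overlapping occurrences of the motif (both strands by default)
    across ``sequences``, then draws ``reps`` uniform letter permutations
    of the motif (with replacement, duplicates allowed) and counts each.
    p = (M+1)/(reps+1) with M the number of shuffles at least as common as
    the original. Motifs shorter than 3 letters or with fewer than two
    distinct letters are rejected (all shuffles would be identical).
    """
    motif = motif.upper()
    if len(motif) < 3:
        raise ValueError("motif must be at least 3 letters")
    if len(set(motif)) < 2:
        raise ValueError("homopolymer motif: shuffling is degenerate")
    rng = np.random.default_rng() if rng is None else rng
    motif_codes = encode_sequence(motif)
    if (motif_codes < 0).any():
        raise ValueError("motif must be ACGT only")
    k = len(motif)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)

    if k <= 12:
        table = np.zeros(4**k, dtype=np.int64)
        for seq in sequences:
            codes = encode_sequence(seq)
            table += _kmer_counts(codes, k)
            if both_strands:
                table += _kmer_counts(_revcomp_codes(codes), k)
        def count(codes: np.ndarray) -> int:
            return int(table[int((codes.astype(np.int64) * powers).sum())])
    else:  # pragma: no cover - long motifs
        encoded = [encode_sequence(s) for s in sequences]
        def count(codes: np.ndarray) -> int:
            tot = 0
            for c in encoded:
                tot += _count_motif(c, codes)
                if both_strands:
                    tot += _count_motif(_revcomp_codes(c), codes)
            return tot

    observed = count(motif_codes)
    shuffles = rng.permuted(np.tile(motif_codes, (reps, 1)), axis=1)
    cache: dict[bytes, int] = {}
    m = 0
    for row in shuffles:
        key = row.tobytes()
        if key not in cache:
            cache[key] = count(row)
        if cache[key] >= observed:
            m += 1
    return observed, (m + 1) / (reps + 1)


# ---------------------------------------------------------------------------
# GC-biased gene conversion


def conversion_gc_bias(
    recipient: np.ndarray,
    donor: np.ndarray,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """u/v statistic of GC-biased gene conversion over converted sites.

    ``recipient``/``donor`` are allele codes per converted marker site (the
    allele overwritten and the allele written in). u is the number of
    AT->GC conversions per A/T recipient base, v the number of GC->AT
    conversions per G/C recipient base. The null flips each site's
    direction with probability 1/2 (``reps`` times); the two-sided
    empirical p compares |log u/v| with the null.
    """
    recipient = np.asarray(recipient)
    donor = np.asarray(donor)
    if len(recipient) == 0:
        raise ValueError("no converted sites")
    rng = np.random.default_rng() if rng is None else rng
    r_gc = is_gc(recipient)
    d_gc = is_gc(donor)
    informative = r_gc != d_gc  # only AT<->GC changes carry signal
    at_to_gc = (~r_gc & d_gc)
    gc_to_at = (r_gc & ~d_gc)
    n_at = int((~r_gc).sum())
    n_gc = int(r_gc.sum())
    if n_at == 0 or n_gc == 0:
        raise ValueError("no opportunity bases in one direction")
    u = at_to_gc.sum() / n_at
    v = gc_to_at.sum() / n_gc
    if v == 0 or u == 0:
        raise ValueError("u/v undefined: a direction has zero conversions")
    obs = float(u / v)

    n_inf = int(informative.sum())
    # null: each informative site converts toward GC or AT with equal odds;
    # opportunity denominators change accordingly (recipient flips too)
    n_rest_at = int((~r_gc & ~informative).sum())
    n_rest_gc = int((r_gc & ~informative).sum())
    toward_gc = rng.random((reps, n_inf)) < 0.5
    k_gc = toward_gc.sum(axis=1)            # sites converting AT->GC
    k_at = n_inf - k_gc
    u0 = k_gc / (n_rest_at + k_gc)
    v0 = k_at / (n_rest_gc + k_at)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio0 = np.where((u0 > 0) & (v0 > 0), u0 / v0, np.nan)
    valid = ratio0[~np.isnan(ratio0)]
    # doubled-tail empirical p around the null's own distribution (the null
    # ratio is not centred at 1 when within-class recipient counts differ)
    n_valid = len(valid)
    m_hi = int((valid >= obs).sum())
    m_lo = int((valid <= obs).sum())
    p = min(1.0, 2.0 * min(m_hi + 1, m_lo + 1) / (n_valid + 1))
    return {"u": float(u), "v": float(v), "ratio": obs, "p": float(p), "n_sites": len(recipient)}


# ---------------------------------------------------------------------------
# marker downsampling


def marker_downsampling(
    colony,
    n_grid: Sequence[int],
    reps: int = 3,
    rng: np.random.Generator | None = None,
    co_min_span: int = 10_000,
    error_tolerance: int = 0,
) -> pd.DataFrame:
    """Estimated genome-wide cM/Mb as a function of marker count.

    For each n, draws ``reps`` random marker subsets, re-phases, re-calls
    crossovers in the drones and reports the mean estimated rate. Rates
    collapse when density drops so low that adjacent crossovers merge.
    """
    from .events import call_drone_events, crossover_rate
    from .markers import FilteredMarkers
    from .phasing import phase_colony

    rng = np.random.default_rng() if rng is None else rng
    genome_mb = sum(colony.queen.chrom_lengths) / 1e6
    n_gametes = len(colony.drone_names)
    full_keep = {
        c: np.ones(len(colony.queen.positions[c]), dtype=bool)
        for c in colony.queen.chrom_names
    }
    totals = {c: len(colony.queen.positions[c]) for c in colony.queen.chrom_names}
    n_total = sum(totals.values())
    rows = []
    for n in n_grid:
        n = min(int(n), n_total)
        rates = []
        for _ in range(reps):
            chosen = rng.choice(n_total, size=n, replace=False)
            keep = {}
            offset = 0
            for c in colony.queen.chrom_names:
                mask = np.zeros(totals[c], dtype=bool)
                local = chosen[(chosen >= offset) & (chosen < offset + totals[c])] - offset
                mask[local] = True
                keep[c] = mask
                offset += totals[c]
            sub = FilteredMarkers.from_colony(colony, keep)
            # chromosomes left without markers carry no linkage information
            populated = tuple(c for c in sub.chrom_names if len(sub.positions[c]))
            sub.chrom_names = populated
            phased = phase_colony(sub)
            ev, _ = call_drone_events(
                sub, phased, co_min_span=co_min_span, error_tolerance=error_tolerance
            )
            n_co = int((ev["kind"] == "CO").sum())
            rates.append(crossover_rate(n_co, genome_mb, n_gametes))
        rows.append((n, float(np.mean(rates)) if rates else np.nan, len(rates)))
    return pd.DataFrame(rows, columns=["n_markers", "rate", "n_reps"])


# ---------------------------------------------------------------------------
# gene-set proximity enrichment


@dataclass
class EnrichmentResult:
    """2x2 chi-square of gene-set proximity to crossover breakpoints."""

    set_name: str
    n_near: int
    n_far: int
    bg_near: int
    bg_far: int
    chi2: float
    p: float

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.n_near, self.n_far], [self.bg_near, self.bg_far]])


def enrichment_from_counts(
    n_near: int, n_total: int, bg_near: int, bg_total: int, set_name: str = ""
) -> EnrichmentResult:
    """Chi-square on a 2x2 near/far table (no continuity correction)."""
    table = np.array(
        [[n_near, n_total - n_near], [bg_near, bg_total - bg_near]]
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(
        set_name, n_near, n_total - n_near, bg_near, bg_total - bg_near,
        float(chi2), float(p),
    )


def proximity_enrichment(
    genes: pd.DataFrame,
    set_ids: Sequence[str],
    breakpoints: pd.DataFrame,
    distance: int = 10_000,
    background_ids: Sequence[str] | None = None,
    set_name: str = "",
) -> EnrichmentResult:
    """Is a gene set enriched near crossover breakpoints?

    ``genes`` needs columns chrom, start, end, gene_id. A gene is *near*
    when its interval comes within ``distance`` bp of any crossover
    breakpoint interval. The background defaults to all genes not in the
    set (whole-genome comparison); pass ``background_ids`` for a matched
    background.
    """
    set_ids = set(set_ids)
    if not set_ids:
        raise ValueError("empty gene set")
    near = _near_mask(genes, breakpoints, distance)
    in_set = genes["gene_id"].isin(set_ids).to_numpy()
    if background_ids is None:
        bg = ~in_set
    else:
        bg = genes["gene_id"].isin(set(background_ids)).to_numpy()
    return enrichment_from_counts(
        int(near[in_set].sum()), int(in_set.sum()),
        int(near[bg].sum()), int(bg.sum()),
        set_name=set_name,
    )


def _near_mask(genes: pd.DataFrame, breakpoints: pd.DataFrame, distance: int) -> np.ndarray:
    near = np.zeros(len(genes), dtype=bool)
    co = breakpoints[breakpoints["kind"] == "CO"] if "kind" in breakpoints else breakpoints
    for chrom, grp in co.groupby("chrom", sort=False):
        sel = np.flatnonzero((genes["chrom"] == chrom).to_numpy())
        if len(sel) == 0:
            continue
        bs = np.sort(grp["start"].to_numpy() - distance)
        be = np.sort(grp["end"].to_numpy() + distance)
        gs = genes.iloc[sel]["start"].to_numpy()
        ge = genes.iloc[sel]["end"].to_numpy()
        # overlap exists iff some breakpoint start <= gene end and its end >= gene start
        # count intervals starting before gene end minus intervals ending before gene start
        n_start_before = np.searchsorted(bs, ge, side="right")
        n_end_before = np.searchsorted(be, gs, side="left")
        near[sel] = n_start_before > n_end_before
    return near
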
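"""Landscape statistics: windows, hotspots, GC coupling, motifs, u/v."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dronemap import landscape as ls
from dronemap.simulate import (
    SimulationConfig,
    simulate_biased_conversions,
    simulate_colony,
    synthesize_reference,
)


def _co_frame(chrom, midpoints):
    mid = np.asarray(midpoints)
    return pd.DataFrame(
        {"chrom": chrom, "kind": "CO", "start": mid, "end": mid, "midpoint": mid}
    )


def test_window_rate_formula_and_empty_windows():
    windows = ls.make_windows({"Chr1": 600_000}, 200_000)
    events = _co_frame("Chr1", [50_000, 150_000])
    out = ls.window_rates(events, windows, n_gametes=43)
    # 2 crossovers among 43 gametes in one 200 kb window
    assert out.loc[0, "rate"] == pytest.approx(100 * (2 / 43) / 0.2, abs=0.05)
    assert out.loc[1, "rate"] == 0.0
    assert out["co_count"].sum() == len(events)


def test_window_counts_conserve_events(clean_colony):
    colony, results = clean_colony
    lengths = dict(zip(colony.queen.chrom_names, colony.queen.chrom_lengths))
    windows = ls.make_windows(lengths, 200_000)
    out = ls.window_rates(results.drone_events, windows, len(colony.drone_names))
    assert out["co_count"].sum() == (results.drone_events["kind"] == "CO").sum()


def test_poisson_tail_closed_forms():
    windows = ls.make_windows({"Chr1": 2_000_000}, 200_000)
    counts = np.array([0, 1, 1, 2, 2, 2, 2, 2, 2, 2])  # mean 1.6
    windows["co_count"] = counts
    windows["rate"] = 0.0
    out = ls.hotspot_test(windows)
    lam = counts.mean()
    assert out.loc[0, "p_cold"] == pytest.approx(np.exp(-lam))
    # e^-1.6 = 0.20 > 0.05: an empty window is not cold at this density
    assert not out.loc[0, "cold_raw"]
    # k equal to the mean is significant in neither tail
    mid = out[out["co_count"] == 2].iloc[0]
    assert mid["p_hot"] > 0.05 and mid["p_cold"] > 0.05


def test_hot_region_merging():
    windows = ls.make_windows({"Chr1": 1_000_000}, 200_000)
    windows["hot_raw"] = [True, True, False, True, False]
    regions = ls.merge_regions(windows, "hot_raw")
    assert len(regions) == 2
    assert regions.loc[0, "end"] - regions.loc[0, "start"] == 400_000


@pytest.fixture(scope="module")
def small_reference():
    cfg = SimulationConfig(
        n_chromosomes=2,
        chrom_lengths=(2_000_000, 1_000_000),
        seed=31,
        cnv_fraction=0.0,
    )
    colony = simulate_colony(cfg)
    rng = np.random.default_rng(31)
    return colony, synthesize_reference(colony.queen, rng)


def test_gc_profile_recovers_planted_islands(small_reference):
    colony, _ = small_reference
    rng = np.random.default_rng(42)
    gc_prof = {
        c: np.full(int(np.ceil(L / 2000)), 0.30)
        for c, L in zip(colony.queen.chrom_names, colony.queen.chrom_lengths)
    }
    islands = rng.choice(np.arange(10, 990), size=40, replace=False)
    gc_prof["Chr1"][islands] = 0.55
    ref = synthesize_reference(colony.queen, rng, gc=gc_prof)
    bp = pd.DataFrame({"chrom": "Chr1", "midpoint": islands * 2000 + 1000, "kind": "CO"})
    profile, p = ls.gc_breakpoint_profile(ref, bp, reps=500, rng=rng)
    central = profile.loc[profile["offset"] == 0, "gc"].iloc[0]
    flank = profile.loc[profile["offset"].abs() >= 3, "gc"].mean()
    assert central > flank + 0.15
    assert p <= 1 / 501 + 1e-9  # not one null as extreme as the observed


def test_gc_profile_null_p_is_unbiased(small_reference):
    _, ref = small_reference
    rng = np.random.default_rng(7)
    lengths = {c: len(s) for c, s in ref.items()}
    tot = sum(lengths.values())
    ps = []
    for _ in range(25):
        pos = rng.integers(5000, tot - 5000, size=50)
        chrom = np.where(pos <= lengths["Chr1"], "Chr1", "Chr2")
        mid = np.where(pos <= lengths["Chr1"], pos, pos - lengths["Chr1"])
        bp = pd.DataFrame({"chrom": chrom, "midpoint": mid, "kind": "CO"})
        _, p = ls.gc_breakpoint_profile(ref, bp, reps=100, rng=rng)
        ps.append(p)
    assert 0.3 < np.mean(ps) < 0.7


def test_gc_rate_relation_signs_and_bin_exclusions(rng):
    n = 4000
    gc = rng.uniform(0.2, 0.5, size=n)
    windows = pd.DataFrame(
        {
            "gc": gc,
            "rate": 200 * (gc - 0.2) + rng.normal(0, 3, size=n),
            "n_fraction": 0.0,
        }
    )
    rho, p, table = ls.gc_rate_relation(windows, min_windows_per_bin=50)
    assert rho > 0.5 and p < 1e-10
    assert (table["n_windows"] >= 50).all()
    assert table.attrs["rate_per_gc_percent"] > 0
    # a flat landscape shows no correlation
    flat = windows.assign(rate=rng.normal(10, 1, size=n))
    rho0, p0, _ = ls.gc_rate_relation(flat, min_windows_per_bin=50)
    assert abs(rho0) < 0.05
    # bins below the occupancy threshold are dropped
    sparse = windows.copy()
    sparse.loc[: n - 60, "gc"] = 0.30  # all but ~60 windows in one bin
    _, _, t2 = ls.gc_rate_relation(sparse, min_windows_per_bin=100)
    assert (t2["n_windows"] >= 100).all()


def test_covariate_correlations_recover_planted_signs(rng):
    n = 3000
    rate = rng.gamma(2, 10, size=n)
    wdf = pd.DataFrame(
        {
            "rate": rate,
            "diversity": rate * 0.001 + rng.normal(0, 0.005, n),
            "gene_count": np.maximum(10 - 0.2 * rate + rng.normal(0, 1, n), 0),
            "cnv_bp": rng.permutation(rate),  # decoupled
        }
    )
    out = ls.covariate_correlations({10_000: wdf})
    rows = out.set_index("covariate")
    assert rows.loc["diversity", "rho"] > 0.3
    assert rows.loc["gene_count", "rho"] < -0.3
    assert abs(rows.loc["cnv_bp", "rho"]) < 0.05


def test_motif_shuffle_validation_and_planted_signal(rng):
    with pytest.raises(ValueError):
        ls.motif_shuffle_test("AAAAA", ["ACGT" * 100])
    with pytest.raises(ValueError):
        ls.motif_shuffle_test("AC", ["ACGT" * 100])
    parts = []
    for _ in range(60):
        parts.append("".join(rng.choice(list("ACGT"), size=300)))
        parts.append("GATCGAT")
    obs, p = ls.motif_shuffle_test("GATCGAT", ["".join(parts)], reps=500, rng=rng)
    assert obs >= 60
    assert p < 0.02


def test_c_rich_motif_not_enriched_in_random_sequence(rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=2000)) for _ in range(300)]
    obs, p = ls.motif_shuffle_test("CCTCCCC", seqs, reps=1000, rng=rng)
    assert p > 0.05  # no enrichment signal in composition-neutral sequence


def test_conversion_gc_bias_null_and_planted():
    rng = np.random.default_rng(3)
    rec, don = simulate_biased_conversions(250, rng, gc_bias=0.5)
    out = ls.conversion_gc_bias(rec, don, reps=2000, rng=rng)
    assert 0.7 < out["ratio"] < 1.4
    assert out["p"] > 0.05
    rec, don = simulate_biased_conversions(250, rng, gc_bias=0.6)
    out = ls.conversion_gc_bias(rec, don, reps=2000, rng=rng)
    assert out["ratio"] > 1.0 and out["p"] < 0.05
    with pytest.raises(ValueError):
        ls.conversion_gc_bias(np.array([]), np.array([]))


def test_marker_downsampling_curve(clean_colony):
    colony, results = clean_colony
    rng = np.random.default_rng(17)
    genome_mb = sum(colony.queen.chrom_lengths) / 1e6
    full = results.markers.n_markers
    curve = ls.marker_downsampling(
        colony, n_grid=[full, 2000, 30], reps=2, rng=rng
    )
    full_rate = results.co_rate(genome_mb, len(colony.drone_names))
    assert curve.loc[0, "rate"] == pytest.approx(full_rate, rel=0.02)
    # ~30 markers genome-wide: the map collapses far below the true rate
    assert curve.loc[2, "rate"] < 0.5 * full_rate
    # the curve does not rise as markers are removed (small sampling slack)
    assert curve.loc[1, "rate"] <= curve.loc[0, "rate"] * 1.03
    assert curve.loc[2, "rate"] < curve.loc[1, "rate"]


def test_proximity_enrichment_counts_and_errors(rng):
    genes = pd.DataFrame(
        {
            "chrom": "Chr1",
            "start": np.arange(100) * 50_000 + 1,
            "end": np.arange(100) * 50_000 + 2_000,
            "gene_id": [f"g{i}" for i in range(100)],
        }
    )
    bp = _co_frame("Chr1", [8_000])  # 6 kb beyond g0's end, far from the rest
    res = ls.proximity_enrichment(genes, ["g0", "g1"], bp, distance=10_000)
    assert res.n_near == 1 and res.n_far == 1
    with pytest.raises(ValueError):
        ls.proximity_enrichment(genes, [], bp)


def test_enrichment_worked_counts_are_overwhelming():
    res = ls.enrichment_from_counts(173, 579, 69, 516, "worker-brain-bias")
    assert res.chi2 > 40
    assert res.p < 1e-9
    # a set drawn like the background is unremarkable
    null = ls.enrichment_from_counts(30, 200, 75, 500)
    assert null.p > 0.5
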
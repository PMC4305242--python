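"""Event calling: segmentation, CO/conversion classification, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dronemap import events as ev
from dronemap.phasing import PhasedHaplotypes


def _phased(positions, hap0=None, hap1=None):
    n = len(positions)
    hap0 = np.zeros(n, dtype=np.int8) if hap0 is None else hap0
    hap1 = np.full(n, 2, dtype=np.int8) if hap1 is None else hap1
    empty = np.zeros(max(n - 1, 0), dtype=bool)
    return PhasedHaplotypes(
        "Chr1", np.asarray(positions), hap0, hap1,
        np.zeros(max(n - 1, 0), dtype=np.int64),
        np.zeros(max(n - 1, 0), dtype=np.int64),
        empty.copy(), empty.copy(), empty.copy(),
    )


def _codes_from_labels(labels, phased):
    labels = np.asarray(labels)
    return np.where(labels == 0, phased.hap0, phased.hap1).astype(np.int8)


def test_uniform_gamete_is_one_block():
    positions = np.arange(1, 20) * 300
    phased = _phased(positions)
    blocks = ev.segment_blocks(positions, phased, phased.hap0.copy(), error_tolerance=0)
    assert len(blocks) == 1
    assert blocks.loc[0, "n_markers"] == 19


def test_single_switch_gives_two_blocks_one_crossover():
    positions = np.arange(1, 21) * 3000
    phased = _phased(positions)
    labels = [0] * 10 + [1] * 10
    blocks = ev.segment_blocks(
        positions, phased, _codes_from_labels(labels, phased), error_tolerance=0
    )
    assert len(blocks) == 2
    events = ev.classify_events(blocks)
    assert list(events["kind"]) == ["CO"]
    assert events.loc[0, "start"] == positions[9]
    assert events.loc[0, "end"] == positions[10]


def test_error_tolerance_smooths_singletons_but_keeps_pairs():
    positions = np.arange(1, 16) * 300
    phased = _phased(positions)
    labels = [0] * 7 + [1] + [0] * 7          # lone discordant site
    blocks = ev.segment_blocks(
        positions, phased, _codes_from_labels(labels, phased), error_tolerance=2
    )
    assert len(blocks) == 1                    # smoothed away
    blocks = ev.segment_blocks(
        positions, phased, _codes_from_labels(labels, phased), error_tolerance=0
    )
    assert len(blocks) == 3                    # kept as a 1-marker tract
    labels = [0] * 7 + [1, 1] + [0] * 6        # two-marker tract survives e=2
    blocks = ev.segment_blocks(
        positions, phased, _codes_from_labels(labels, phased), error_tolerance=2
    )
    assert len(blocks) == 3


def test_span_boundary_is_strict():
    # interior block of span exactly 10,001 bp -> crossover side of the rule
    positions = np.array([1000, 15000, 29999, 40000, 50001, 80000, 120000])
    phased = _phased(positions)
    labels = [0, 0, 0, 1, 1, 0, 0]
    blocks = ev.segment_blocks(
        positions, phased, _codes_from_labels(labels, phased), error_tolerance=0
    )
    assert blocks.loc[1, "span"] == 10_001
    events = ev.classify_events(blocks, co_min_span=10_000)
    assert (events["kind"] == "CO").sum() == 2  # the 10,001 bp block anchors
    # at a 10,001 bp cutoff the same block is a conversion instead
    events = ev.classify_events(blocks, co_min_span=10_001)
    assert (events["kind"] == "CO").sum() == 0
    assert (events["kind"] == "NCO_conversion").sum() == 1


def test_interleaved_pattern_is_one_co_associated_conversion():
    # 1...1 22 11 2...2 with the distal short block 8 kb from the CO edge
    positions = np.concatenate(
        [
            np.arange(1, 31) * 1000,          # anchor haplotype 0: 1-30 kb
            [31_000, 31_400],                 # short tract of haplotype 1
            [32_000, 32_500],                 # short return to haplotype 0
            np.arange(39, 70) * 1000,         # crossover block: haplotype 1
        ]
    )
    phased = _phased(positions)
    labels = [0] * 30 + [1, 1] + [0, 0] + [1] * 31
    blocks = ev.segment_blocks(
        positions, phased, _codes_from_labels(labels, phased), error_tolerance=0
    )
    events = ev.classify_events(blocks, co_min_span=10_000)
    events = ev.associate_conversions(events, blocks)
    kinds = events["kind"].value_counts().to_dict()
    assert kinds == {"CO": 1, "CO_conversion": 1}
    conv = events[events["kind"] == "CO_conversion"].iloc[0]
    assert conv["start"] == 31_000 and conv["end"] == 32_500


def test_isolated_short_block_is_nco_conversion():
    # 11*22*11...1 far from any crossover
    positions = np.concatenate(
        [np.arange(1, 41) * 1000, [41_000, 41_500], np.arange(60, 100) * 1000]
    )
    phased = _phased(positions)
    labels = [0] * 40 + [1, 1] + [0] * 40
    blocks = ev.segment_blocks(
        positions, phased, _codes_from_labels(labels, phased), error_tolerance=0
    )
    events = ev.associate_conversions(ev.classify_events(blocks), blocks)
    assert list(events["kind"]) == ["NCO_conversion"]


def test_terminal_short_blocks_generate_no_event():
    positions = np.concatenate([[500, 900], np.arange(15, 60) * 1000])
    phased = _phased(positions)
    labels = [1, 1] + [0] * 45
    blocks = ev.segment_blocks(
        positions, phased, _codes_from_labels(labels, phased), error_tolerance=0
    )
    assert len(ev.classify_events(blocks)) == 0


@settings(max_examples=60, deadline=None)
@given(
    spans=st.lists(st.integers(min_value=200, max_value=120_000), min_size=1, max_size=12)
)
def test_raising_threshold_never_increases_crossovers(spans):
    """CO count is monotone non-increasing in the conversion-span cutoff."""
    positions = [1000]
    labels = []
    for i, span in enumerate(spans):
        n = max(span // 3000, 1) + 1
        start = positions[-1] + 500
        positions.extend(np.linspace(start, start + span, n).astype(int))
        labels.extend([i % 2] * n)
    positions = np.array(positions[1:])
    phased = _phased(positions)
    blocks = ev.segment_blocks(
        positions, phased, _codes_from_labels(labels, phased), error_tolerance=0
    )
    counts = [
        (ev.classify_events(blocks, co_min_span=t)["kind"] == "CO").sum()
        for t in (1_000, 10_000, 20_000, 100_000)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_blocks_are_ordered_alternating_nonoverlapping(clean_colony):
    _, results = clean_colony
    for (_, _), grp in results.drone_blocks.groupby(["gamete", "chrom"], sort=False):
        first = grp["first_pos"].to_numpy()
        last = grp["last_pos"].to_numpy()
        labels = grp["label"].to_numpy()
        assert (first <= last).all()
        assert (first[1:] > last[:-1]).all()
        assert (labels[1:] != labels[:-1]).all()


def test_truth_breakpoints_fall_inside_called_intervals(clean_colony):
    colony, results = clean_colony
    lengths = dict(zip(colony.queen.chrom_names, colony.queen.chrom_lengths))
    truth = colony.truth.events
    tco = truth[(truth["kind"] == "CO") & truth["gamete"].str.startswith("drone")]
    called = results.drone_events[results.drone_events["kind"] == "CO"]
    hit = total = 0
    for _, r in tco.iterrows():
        if not (10_000 < r["breakpoint"] < lengths[r["chrom"]] - 10_000):
            continue  # terminal blocks are uncallable by construction
        total += 1
        sub = called[
            (called["gamete"] == r["gamete"])
            & (called["chrom"] == r["chrom"])
            & (called["start"] <= r["breakpoint"])
            & (called["end"] >= r["breakpoint"])
        ]
        hit += bool(len(sub))
    assert hit / total >= 0.99


def test_relabeling_haplotypes_leaves_events_invariant(clean_colony):
    colony, results = clean_colony
    chrom = colony.queen.chrom_names[0]
    m = results.markers
    hp = results.phased[chrom]
    swapped = PhasedHaplotypes(
        chrom, hp.positions, hp.hap1, hp.hap0, hp.n_parallel, hp.n_cross,
        hp.tie, hp.gap_adjacent, hp.near_even,
    )
    for d in range(3):
        codes = m.drone_alleles[chrom][d]
        b1 = ev.segment_blocks(m.positions[chrom], hp, codes, error_tolerance=0)
        b2 = ev.segment_blocks(m.positions[chrom], swapped, codes, error_tolerance=0)
        e1 = ev.classify_events(b1)
        e2 = ev.classify_events(b2)
        pd.testing.assert_frame_equal(
            e1.drop(columns=[]), e2.drop(columns=[])
        )


def test_exclusion_filters_remove_planted_conflicts():
    events = pd.DataFrame(
        {
            "gamete": ["d1"] * 4,
            "chrom": ["Chr1"] * 4,
            "kind": ["NCO_conversion", "NCO_conversion", "CO", "NCO_conversion"],
            "start": [10_000, 50_000, 200_000, 300_000],
            "end": [10_500, 50_400, 201_000, 300_600],
            "midpoint": [10_250.0, 50_200.0, 200_500.0, 300_300.0],
            "n_markers": [2, 2, 0, 2],
            "span": [500, 400, 1000, 600],
            "flank_left": [9_000, 49_000, 200_000, 299_000],
            "flank_right": [11_000, 51_000, 201_000, 301_500],
        }
    )
    gaps = {"Chr1": np.array([[10_400, 10_900]])}
    multicopy = pd.DataFrame({"chrom": ["Chr1"], "start": [50_100], "end": [52_000]})
    kept, removed = ev.exclusion_filters(events, gaps=gaps, multicopy=multicopy)
    reasons = dict(zip(removed["start"], removed["reason"]))
    assert reasons == {10_000: "gap", 50_000: "cnv_mask"}
    # the isolated crossover is kept even though nothing vouches for it
    assert set(kept["kind"]) == {"CO", "NCO_conversion"}
    # read-evidence predicates remove flagged events
    kept2, removed2 = ev.exclusion_filters(
        events, read_uninterrupted=lambda e: e["start"] != 300_000
    )
    assert list(removed2["start"]) == [300_000]
    assert list(removed2["reason"]) == ["read_interrupted"]


def test_worker_haplotype_resolution_rules():
    alleles = np.array([[0, 2]] * 4, dtype=np.int8)  # queen A/G
    pairs = np.array(
        [
            [0, 0],  # hom A/A -> queen allele A
            [0, 2],  # het equal to queen pair -> unresolved
            [2, 3],  # het G/T -> G matches the queen pair
            [1, 3],  # neither allele matches -> unresolved
        ],
        dtype=np.int8,
    )
    resolved = ev.resolve_worker_haplotype(alleles, pairs)
    assert resolved.tolist() == [0, -1, 2, -1]


def test_worker_and_drone_co_counts_agree(clean_colony):
    _, results = clean_colony
    stat, p = ev.worker_drone_concordance(
        results.drone_co_counts().to_numpy(),
        results.worker_co_counts().to_numpy(),
        method="mann-whitney",
    )
    assert p > 0.05


def test_multicopy_conversion_switch_rule():
    positions = {"Chr1": np.array([1000, 1400, 1800, 2200, 2600, 3000])}
    regions = pd.DataFrame({"chrom": ["Chr1"], "start": [900], "end": [3100]})
    from dronemap._alleles import HET

    base = np.zeros((4, 6), dtype=np.int8)
    base[0] = HET                    # constant-het pattern (dup haplotype)
    base[1] = 0                      # constant-hom pattern
    base[2] = [HET, HET, HET, 0, 0, 0]   # three-site switch -> candidate
    base[3] = [HET, HET, HET, HET, HET, 0]  # single switched site -> none
    calls = ev.call_multicopy_conversions({"Chr1": base}, positions, regions)
    assert len(calls) == 1
    row = calls.iloc[0]
    assert row["gamete"] == "drone3"
    assert (row["start"], row["end"]) == (2200, 3000)
    # a region where all drones share one pattern yields nothing
    uniform = np.zeros((3, 6), dtype=np.int8)
    assert len(ev.call_multicopy_conversions({"Chr1": uniform}, positions, regions)) == 0


def test_shared_crossover_grouping():
    events = pd.DataFrame(
        {
            "gamete": ["d1", "d2", "d3"],
            "chrom": ["Chr1"] * 3,
            "kind": ["CO"] * 3,
            "start": [1000, 1500, 9000],
            "end": [2000, 2600, 9500],
            "midpoint": [1500.0, 2050.0, 9250.0],
        }
    )
    out = ev.annotate_shared(events)
    assert out.loc[0, "shared_count"] == 2
    assert out.loc[1, "shared_count"] == 2
    assert out.loc[2, "shared_count"] == 1


def test_crossover_rate_formula():
    assert ev.crossover_rate(81.5, 220.0, 1) == pytest.approx(37.0, abs=0.1)
    assert ev.crossover_rate(81.5, 219.6, 1) == pytest.approx(37.1, abs=0.05)
    assert ev.crossover_rate(0, 220.0, 43) == 0.0
    with pytest.raises(ValueError):
        ev.crossover_rate(10, 220.0, 0)


def test_worked_example_arithmetic():
    from dronemap.datasets import STUDY

    mult = STUDY["shared_co_multiplicity"]
    assert ev.shared_event_total(mult) == 1260
    assert STUDY["total_conversions"] - STUDY["co_associated_conversions"] == 221
    assert ev.co_associated_fraction(29, 3505) == pytest.approx(0.008, abs=5e-4)
    assert ev.co_associated_fraction(43, 3505) == pytest.approx(0.012, abs=5e-4)
    assert ev.conversions_per_gamete(250, 45, 43) == pytest.approx(6.86, abs=0.01)
    assert ev.extrapolated_conversions_per_gamete(29, 0.1, 221, 43) == pytest.approx(
        11.88, abs=0.01
    )


def test_rate_excluding_modes(clean_colony):
    colony, results = clean_colony
    genome_mb = sum(colony.queen.chrom_lengths) / 1e6
    n = len(colony.drone_names)
    base = results.co_rate(genome_mb, n)
    dropped = ev.rate_excluding(results.drone_events, genome_mb, n, "drop_shared")
    assert 0 < dropped <= base
    multi = ev.rate_excluding(
        results.drone_events, genome_mb, n, "drop_multi_co_gap",
        gaps=colony.queen.gaps,
    )
    assert 0 < multi <= base
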
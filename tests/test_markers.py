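"""Marker filtering and multi-copy detection."""

import numpy as np
import pandas as pd
import pytest

from dronemap import markers as mk
from dronemap._alleles import HET, MISSING, encode_base
from dronemap.simulate import SimulationConfig, simulate_colony


def test_call_candidates_keeps_het_snvs_only():
    table = pd.DataFrame(
        {
            "chrom": ["Chr1"] * 4,
            "pos": [100, 200, 300, 400],
            "allele_a": ["A", "A", "AT", "G"],
            "allele_b": ["G", "A", "A", "C"],
            "qual": [50.0, 60.0, 55.0, 20.0],
        }
    )
    cand, report = mk.call_candidates(table)
    assert list(cand["pos"]) == [100, 400]  # het SNVs, any quality
    assert report.not_heterozygous == 1
    assert report.indel_or_multiallelic == 1


@pytest.fixture(scope="module")
def clean_small_colony():
    cfg = SimulationConfig().scaled(
        1 / 40, seed=21, cnv_fraction=0.0, genotype_error_rate=0.0
    )
    return simulate_colony(cfg)


def test_no_removals_without_cnvs_or_errors(clean_small_colony):
    keep, report = mk.apply_filters(clean_small_colony, min_qual=0.0)
    assert report.drone_het == 0
    assert report.allele_mismatch == 0
    assert all(m.all() for m in keep.values())


def test_filter_attribution_and_order_insensitivity(clean_small_colony):
    colony = clean_small_colony
    chrom = colony.queen.chrom_names[0]
    # plant one drone-het site, one off-pair allele, one low-quality site
    colony.drone_alleles[chrom][0, 10] = HET
    pair = set(colony.queen.alleles[chrom][20])
    off = next(c for c in range(4) if c not in pair)
    colony.drone_alleles[chrom][1, 20] = off
    colony.queen.quality[chrom][30] = 10.0
    keep, report = mk.apply_filters(colony)
    assert report.drone_het >= 1 and report.allele_mismatch >= 1
    assert not keep[chrom][10] and not keep[chrom][20] and not keep[chrom][30]

    # outcome equals the conjunction of the three independent predicates,
    # so any application order leaves the surviving set unchanged
    codes = colony.drone_alleles[chrom]
    alleles = colony.queen.alleles[chrom]
    f2 = ~(codes == HET).any(axis=0)
    obs = codes >= 0
    f3 = ~(
        obs
        & (codes != alleles[None, :, 0])
        & (codes != alleles[None, :, 1])
    ).any(axis=0)
    f4 = colony.queen.quality[chrom] >= 30.0
    for order in [(f2, f3, f4), (f4, f2, f3), (f3, f4, f2)]:
        manual = np.logical_and.reduce(order)
        assert np.array_equal(manual, keep[chrom])
    # restore planted corruption for other tests sharing the fixture
    colony.drone_alleles[chrom][0, 10] = alleles[10, 0]
    colony.drone_alleles[chrom][1, 20] = alleles[20, 0]
    colony.queen.quality[chrom][30] = 50.0


def test_all_removed_raises(clean_small_colony):
    with pytest.raises(mk.MarkerCallingError):
        mk.apply_filters(clean_small_colony, min_qual=1000.0)


def _colony_with_het_sites(positions, het_sites):
    """Minimal one-chromosome colony with dictated drone het sites."""
    from dronemap.simulate import Colony, QueenGenome, TruthSet

    pos = np.asarray(positions, dtype=np.int64)
    n = len(pos)
    alleles = np.tile(np.array([[0, 2]], dtype=np.int8), (n, 1))
    queen = QueenGenome(
        chrom_names=("Chr1",),
        chrom_lengths=(int(pos[-1]) + 1000,),
        positions={"Chr1": pos},
        alleles={"Chr1": alleles},
        quality={"Chr1": np.full(n, 60.0)},
        gaps={"Chr1": np.empty((0, 2), dtype=np.int64)},
    )
    drones = np.zeros((2, n), dtype=np.int8)
    for i in het_sites:
        drones[0, i] = HET
    cfg = SimulationConfig(n_chromosomes=1, chrom_lengths=queen.chrom_lengths, n_workers=0)
    truth = TruthSet(pd.DataFrame(), pd.DataFrame(), {}, {}, {})
    return Colony(cfg, queen, ("drone1", "drone2"), (), {"Chr1": drones},
                  {"Chr1": np.empty((0, n, 2), dtype=np.int8)}, truth)


def test_multicopy_chaining_rule():
    # gaps below 2 kb chain into one region
    colony = _colony_with_het_sites([1000, 2500, 4200], [0, 1, 2])
    regions = mk.detect_multicopy(colony)
    assert len(regions) == 1
    assert (regions.loc[0, "start"], regions.loc[0, "end"]) == (1000, 4200)
    assert regions.loc[0, "n_hetsnps"] == 3
    # a 2.5 kb gap breaks the chain; singletons are not regions
    colony = _colony_with_het_sites([1000, 3500], [0, 1])
    assert len(mk.detect_multicopy(colony)) == 0


def test_multicopy_recovery_on_planted_cnvs():
    cfg = SimulationConfig().scaled(1 / 11, seed=22, genotype_error_rate=0.0)
    colony = simulate_colony(cfg)
    regions = mk.detect_multicopy(colony)
    genome = sum(colony.queen.chrom_lengths)
    detected = mk.multicopy_genome_fraction(regions, genome)
    truth = colony.truth.cnv_regions
    truth_frac = (truth["end"] - truth["start"] + 1).sum() / genome
    # detected coverage approximates the planted ~13.5% (boundaries shrink
    # to the outermost het site, so slightly below truth)
    assert 0.7 * truth_frac < detected <= 1.05 * truth_frac
    # and detected bases overwhelmingly lie inside true CNV regions
    inside = 0
    for chrom, grp in regions.groupby("chrom"):
        t = truth[truth["chrom"] == chrom]
        for _, r in grp.iterrows():
            ov = np.minimum(t["end"], r["end"]) - np.maximum(t["start"], r["start"]) + 1
            inside += int(ov.clip(lower=0).sum())
    assert inside / (regions["end"] - regions["start"] + 1).sum() >= 0.9


def test_no_multicopy_false_positives_when_clean(clean_small_colony):
    assert len(mk.detect_multicopy(clean_small_colony)) == 0


def test_heterozygosity_and_spacing():
    assert mk.heterozygosity(671_690, int(199.7e6)) == pytest.approx(0.00336, rel=0.01)
    assert mk.heterozygosity(0, 1000) == 0.0
    assert mk.mean_marker_spacing(219.6e6, 699_972) == pytest.approx(313.7, abs=0.1)
    with pytest.raises(ValueError):
        mk.mean_marker_spacing(1000, 0)


def test_marker_density_estimates_configured_heterozygosity(clean_small_colony):
    colony = clean_small_colony
    h = 1.0 / colony.config.marker_spacing()
    est = mk.heterozygosity(colony.queen.n_markers, sum(colony.queen.chrom_lengths))
    assert abs(est - h) / h < 0.05
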
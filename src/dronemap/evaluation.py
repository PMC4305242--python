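"""Scoring pipeline output against a colony's simulation truth set.

Used by the validation suite: haplotype switch errors, crossover recovery
(restricted to *callable* breakpoints, i.e. those further than the
conversion-span cutoff from chromosome ends -- a crossover closer than
that yields a terminal short block that single-gamete typing cannot
distinguish from a conversion), conversion detection against the
marker-coverage bound, and conversion/crossover confusion counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phasing import switch_error_rate
from .pipeline import ColonyResults
from .simulate import Colony

__all__ = [
    "phasing_switch_errors",
    "crossover_recovery",
    "conversion_recovery",
    "conversions_called_as_crossovers",
]

_CONVERSION_TRUTH_KINDS = ("NCO", "CO_conv_complex", "CO_conv_simple")


def phasing_switch_errors(colony: Colony, results: ColonyResults) -> tuple[int, int]:
    """(number of switch errors, number of adjacent marker pairs)."""
    errors = pairs = 0
    for chrom in colony.queen.chrom_names:
        keep = results.markers.keep_mask[chrom]
        truth0 = colony.queen.alleles[chrom][keep, 0]
        n = len(truth0)
        if n < 2:
            continue
        rate = switch_error_rate(results.phased[chrom], truth0)
        errors += int(round(rate * (n - 1)))
        pairs += n - 1
    return errors, pairs


def crossover_recovery(
    colony: Colony, results: ColonyResults, co_min_span: int = 10_000
) -> tuple[int, int]:
    """(recovered, callable) truth crossovers in drones.

    A truth crossover is recovered when a called CO in the same gamete has
    a flanking-marker interval containing the true breakpoint. *Callable*
    excludes two classes the span rule cannot express as crossovers: a
    breakpoint within ``co_min_span`` of a chromosome end (terminal short
    block), and a breakpoint with a second crossover of the same meiosis
    within ``co_min_span`` (the pair collapses into a short interior block
    that the rule, by design, reads as a conversion tract).
    """
    lengths = dict(zip(colony.queen.chrom_names, colony.queen.chrom_lengths))
    truth = colony.truth.events
    tco = truth[(truth["kind"] == "CO") & truth["gamete"].str.startswith("drone")]
    called = results.drone_events[results.drone_events["kind"] == "CO"]
    by_key = {k: g for k, g in called.groupby(["gamete", "chrom"], sort=False)}
    partner_gap: dict[int, float] = {}
    for (_, _), grp in tco.groupby(["gamete", "chrom"], sort=False):
        bps = np.sort(grp["breakpoint"].to_numpy())
        gaps = np.diff(bps)
        for i, idx in enumerate(grp.sort_values("breakpoint").index):
            left = gaps[i - 1] if i > 0 else np.inf
            right = gaps[i] if i < len(gaps) else np.inf
            partner_gap[idx] = min(left, right)
    hit = total = 0
    for idx, r in tco.iterrows():
        b = r["breakpoint"]
        if not (co_min_span < b < lengths[r["chrom"]] - co_min_span):
            continue
        if partner_gap.get(idx, np.inf) <= co_min_span:
            continue
        total += 1
        grp = by_key.get((r["gamete"], r["chrom"]))
        if grp is not None and ((grp["start"] <= b) & (grp["end"] >= b)).any():
            hit += 1
    return hit, total


def conversion_recovery(
    colony: Colony, results: ColonyResults
) -> tuple[int, int, int]:
    """(detected, marker-covered, total) detectable truth conversion tracts.

    Counts NCO and complex CO-associated tracts in drones; a tract is
    *marker-covered* when at least one retained marker falls inside it
    (the information-theoretic detection bound) and *detected* when a
    called conversion overlaps it in the same gamete.
    """
    truth = colony.truth.events
    tn = truth[
        truth["kind"].isin(["NCO", "CO_conv_complex"])
        & truth["gamete"].str.startswith("drone")
    ]
    conv = results.drone_events[
        results.drone_events["kind"].isin(["NCO_conversion", "CO_conversion"])
    ]
    by_key = {k: g for k, g in conv.groupby(["gamete", "chrom"], sort=False)}
    detected = covered = 0
    for _, r in tn.iterrows():
        pos = results.markers.positions[r["chrom"]]
        if ((pos >= r["start"]) & (pos <= r["end"])).any():
            covered += 1
        grp = by_key.get((r["gamete"], r["chrom"]))
        if grp is not None and (
            (grp["start"] <= r["end"]) & (grp["end"] >= r["start"])
        ).any():
            detected += 1
    return detected, covered, len(tn)


def conversions_called_as_crossovers(
    colony: Colony, results: ColonyResults, margin: int = 10_000
) -> int:
    """Called COs explained by a truth conversion tract and no truth CO.

    A conversion tract adjacent to a real crossover can shift the called
    breakpoint interval off the true position; a truth crossover within
    ``margin`` of the interval therefore still explains the call, and only
    calls with no crossover anywhere near count as misclassified tracts.
    """
    truth = colony.truth.events
    called = results.drone_events[results.drone_events["kind"] == "CO"]
    n_bad = 0
    for _, r in called.iterrows():
        t = truth[(truth["gamete"] == r["gamete"]) & (truth["chrom"] == r["chrom"])]
        has_co = (
            (t["kind"] == "CO")
            & (t["breakpoint"] >= r["start"] - margin)
            & (t["breakpoint"] <= r["end"] + margin)
        ).any()
        overlaps_conv = (
            t["kind"].isin(_CONVERSION_TRUTH_KINDS)
            & (t["start"] <= r["end"])
            & (t["end"] >= r["start"])
        ).any()
        if overlaps_conv and not has_co:
            n_bad += 1
    return n_bad
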
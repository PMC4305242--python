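"""End-to-end colony analysis: markers -> phasing -> events -> rates.

A convenience layer chaining the module stages on an in-memory
:class:`~dronemap.simulate.Colony`; every stage is also callable on its
own for custom workflows.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import events as ev
from . import markers as mk
from . import phasing as ph
from .markers import DiscardReport, FilteredMarkers
from .simulate import Colony

__all__ = ["ColonyResults", "analyze_colony"]


@dataclass
class ColonyResults:
    """All intermediate and final tables for one colony."""

    markers: FilteredMarkers
    discard_report: DiscardReport
    multicopy: pd.DataFrame
    phased: dict[str, ph.PhasedHaplotypes]
    drone_blocks: pd.DataFrame
    drone_events: pd.DataFrame          # kept after exclusion filters
    removed_events: pd.DataFrame
    multicopy_conversions: pd.DataFrame
    worker_events: pd.DataFrame
    worker_summary: pd.DataFrame

    @property
    def n_co(self) -> int:
        return int((self.drone_events["kind"] == "CO").sum())

    def co_rate(self, genome_mb: float, n_gametes: int) -> float:
        return ev.crossover_rate(self.n_co, genome_mb, n_gametes)

    def drone_co_counts(self) -> pd.Series:
        co = self.drone_events[self.drone_events["kind"] == "CO"]
        return co.groupby("gamete").size()

    def worker_co_counts(self) -> pd.Series:
        return self.worker_events.groupby("gamete").size()


def analyze_colony(
    colony: Colony,
    min_qual: float = 30.0,
    co_min_span: int = 10_000,
    proximity: int = 10_000,
    error_tolerance: int = 2,
    mask_multicopy: bool = True,
) -> ColonyResults:
    """Run the full calling pipeline on one colony.

    ``error_tolerance`` is the number of consistent flanking markers
    required to smooth away an isolated discordant site; use 0 on
    error-free data to keep single-marker conversion tracts.
    """
    filtered, report = mk.filter_colony(colony, min_qual=min_qual)
    multicopy = mk.detect_multicopy(colony)
    phased = ph.phase_colony(filtered, gaps=colony.queen.gaps)
    drone_events, blocks = ev.call_drone_events(
        filtered,
        phased,
        co_min_span=co_min_span,
        proximity=proximity,
        error_tolerance=error_tolerance,
    )
    kept, removed = ev.exclusion_filters(
        drone_events,
        gaps=colony.queen.gaps,
        multicopy=multicopy if mask_multicopy else None,
    )
    kept = ev.annotate_shared(kept)
    mc_conv = ev.call_multicopy_conversions(
        colony.drone_alleles,
        colony.queen.positions,
        multicopy,
        drone_names=list(colony.drone_names),
    )
    worker_events, worker_summary = ev.call_worker_events(
        filtered, phased, co_min_span=co_min_span, error_tolerance=error_tolerance
    )
    return ColonyResults(
        markers=filtered,
        discard_report=report,
        multicopy=multicopy,
        phased=phased,
        drone_blocks=blocks,
        drone_events=kept,
        removed_events=removed,
        multicopy_conversions=mc_conv,
        worker_events=worker_events,
        worker_summary=worker_summary,
    )
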
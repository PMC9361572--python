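"""Ks-based divergence dating and polyploidy-event assignment.

Divergence time follows the molecular-clock relation T = Ks / (2 r)
with r a lineage-appropriate neutral substitution rate (substitutions
per site per year); T is reported in Mya.  Paralog pairs are assigned
to polyploidization events by binning their Ks between event anchors —
the modal Ks of the paralog cohort each event created.  Anchor sets and
rates for the Apiaceae study system (celery, coriander, carrot) plus
lettuce and ginseng ship as module constants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RateModel:
    """A neutral substitution rate, substitutions per site per year."""

    name: str
    r: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"rate {self.name!r} must be positive, got {self.r}")


#: neutral rate used within Apiaceae (celery/coriander/carrot comparisons)
APIACEAE_RATE = RateModel("apiaceae", 5.2e-9)
#: general dicot rate, used for celery vs. Arabidopsis and other dicots
DICOT_RATE = RateModel("dicot", 1.5e-8)

#: default lineage map: species -> clade sharing a within-clade rate
DEFAULT_RATE_CONFIG = {
    "clades": {
        "celery": "apiaceae",
        "coriander": "apiaceae",
        "carrot": "apiaceae",
        "arabidopsis": "dicot-outgroup",
        "grape": "dicot-outgroup",
        "lettuce": "dicot-outgroup",
        "ginseng": "dicot-outgroup",
    },
    "within_rate": APIACEAE_RATE,
    "cross_rate": DICOT_RATE,
    "within_clade": "apiaceae",
}


@dataclass(frozen=True)
class EventAnchorSet:
    """Named polyploidization events with their Ks anchors for one genome."""

    genome: str
    anchors: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("anchor set must contain at least one event")
        names = [n for n, _ in self.anchors]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate event names in {self.genome} anchors")
        values = [k for _, k in self.anchors]
        if any(k <= 0 for k in values):
            raise ValueError("anchor Ks values must be positive")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError("anchor Ks values must be strictly increasing")

    @property
    def events(self) -> list[str]:
        return [n for n, _ in self.anchors]

    def interval_labels(self) -> list[str]:
        """All interval labels from youngest (smallest Ks) to oldest."""
        names = self.events
        labels = [f"after_{names[0]}"]
        labels += [f"between_{a}_{b}" for a, b in zip(names, names[1:])]
        labels.append(f"before_{names[-1]}")
        return labels


# Anchor Ks values of the polyploidization events in each study genome:
# the eudicot gamma triplication, the Apiaceae omega and alpha
# duplications (omega varies slightly by genome), and the lettuce (L1)
# and ginseng (G1, G2) lineage-specific events.
CELERY_ANCHORS = EventAnchorSet(
    "celery", (("alpha", 0.3659), ("celery-omega", 0.7154), ("gamma", 1.2560))
)
CORIANDER_ANCHORS = EventAnchorSet(
    "coriander", (("alpha", 0.3659), ("coriander-omega", 0.7194), ("gamma", 1.2560))
)
CARROT_ANCHORS = EventAnchorSet(
    "carrot", (("alpha", 0.3659), ("carrot-omega", 0.7470), ("gamma", 1.2560))
)
LETTUCE_ANCHORS = EventAnchorSet("lettuce", (("L1", 0.6415), ("gamma", 1.2560)))
GINSENG_ANCHORS = EventAnchorSet(
    "ginseng", (("G2", 0.0297), ("G1", 0.2884), ("gamma", 1.2560))
)

BUILTIN_ANCHORS = {
    a.genome: a
    for a in (
        CELERY_ANCHORS,
        CORIANDER_ANCHORS,
        CARROT_ANCHORS,
        LETTUCE_ANCHORS,
        GINSENG_ANCHORS,
    )
}

#: interval colour classes used for three-anchor (four-interval) schemes,
#: youngest interval first
_THREE_ANCHOR_COLORS = ("red", "green", "orange", "blue")


@dataclass(frozen=True)
class TimeEstimate:
    """Divergence time of one pair, T = Ks / (2 r), in Mya."""

    pair_id: str
    ks: float
    rate_name: str
    T: float


@dataclass(frozen=True)
class PairAssignment:
    """One pair's Ks placed into an interval of an event anchor set."""

    pair_id: str
    ks: float
    interval_label: str
    attributed_event: str | None
    color_class: str | None


def divergence_time(ks: float, rate: RateModel, pair_id: str = "") -> TimeEstimate:
    """Convert a Ks value to a divergence time in Mya (NaN propagates)."""
    if not math.isnan(ks) and ks < 0:
        raise ValueError(f"negative ks {ks}")
    T = math.nan if math.isnan(ks) else ks / (2.0 * rate.r) / 1e6
    return TimeEstimate(pair_id=pair_id, ks=ks, rate_name=rate.name, T=T)


def select_rate(species_a: str, species_b: str, config=None) -> RateModel:
    """Pick the neutral rate for a species pair from a lineage map.

    Returns the within-clade rate when both species belong to the
    configured clade, otherwise the cross-clade rate.  Unknown species
    raise ``KeyError``.
    """
    cfg = config or DEFAULT_RATE_CONFIG
    clades = cfg["clades"]
    for sp in (species_a, species_b):
        if sp.lower() not in clades:
            raise KeyError(f"species {sp!r} not in the lineage map")
    a, b = clades[species_a.lower()], clades[species_b.lower()]
    within = cfg["within_clade"]
    if a == within and b == within:
        return cfg["within_rate"]
    return cfg["cross_rate"]


def assign_event(
    ks: float, anchors: EventAnchorSet, pair_id: str = ""
) -> PairAssignment:
    """Place one Ks value into the anchor set's intervals.

    Intervals are (lower, upper] — a Ks exactly at an anchor belongs to
    that anchor's event, since a pair born at the event has exactly its
    Ks.  The attributed event is the upper bounding anchor; a Ks above
    the largest anchor predates the oldest event and gets no
    attribution.  NaN Ks is returned as "unassigned" with a warning.
    """
    if math.isnan(ks):
        logger.warning("pair %s has undefined Ks; left unassigned", pair_id or "?")
        return PairAssignment(pair_id, ks, "unassigned", None, None)
    if ks < 0:
        raise ValueError(f"negative ks {ks}")

    labels = anchors.interval_labels()
    colors = (
        _THREE_ANCHOR_COLORS if len(anchors.anchors) == 3 else (None,) * len(labels)
    )
    for i, (event, anchor_ks) in enumerate(anchors.anchors):
        if ks <= anchor_ks:
            return PairAssignment(pair_id, ks, labels[i], event, colors[i])
    return PairAssignment(pair_id, ks, labels[-1], None, colors[-1])


def bin_pairs(
    kaks_results, anchors: EventAnchorSet
) -> tuple[list[PairAssignment], dict[str, int]]:
    """Assign every pair to an interval and tally per-interval counts.

    ``kaks_results`` may be KaKsResult objects or (pair_id, ks) tuples.
    Counts include every interval label (zero counts kept) plus an
    "unassigned" bucket for NaN Ks.
    """
    counts: dict[str, int] = {label: 0 for label in anchors.interval_labels()}
    counts["unassigned"] = 0
    assignments: list[PairAssignment] = []
    for item in kaks_results:
        if hasattr(item, "pair_id"):
            pair_id, ks = item.pair_id, item.ks
        else:
            pair_id, ks = item
        asg = assign_event(ks, anchors, pair_id=pair_id)
        assignments.append(asg)
        counts[asg.interval_label] += 1
    return assignments, counts
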
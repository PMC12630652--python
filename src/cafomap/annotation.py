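"""Facility lifetime bounds, animal-type resolution, and rater agreement.

Facility lifetimes are bracketed from yearly presence/absence observations
in dated imagery: construction is bounded by the latest image without the
facility and the earliest image with it, destruction by the latest image
with it and the earliest without it.  Facilities present throughout the
observed record carry only a construction upper bound.

Animal types come from permit linkage where possible (an unambiguous match
to cattle-program permits implies a cattle facility) and from human
annotation otherwise; the dairy label is always a refinement of cattle.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

__all__ = [
    "Observation",
    "DateBounds",
    "LifetimeProfile",
    "AnimalTypeLabel",
    "LabelDecision",
    "bounds_from_yearly_observations",
    "classify_lifetime_profile",
    "resolve_animal_type",
    "cohens_kappa",
]

ANIMAL_TYPES = frozenset({"cattle", "dairy", "poultry", "hog", "other", "unknown"})


class Observation(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    NO_IMAGE = "no_image"


class LifetimeProfile(str, Enum):
    CONSTRUCTION_ONLY = "construction_only"
    DESTRUCTION_ONLY = "destruction_only"
    BOTH = "both"
    NEITHER = "neither"


@dataclass(frozen=True)
class DateBounds:
    """Year-granularity interval bounds on construction and destruction.

    Every facility has a construction upper bound (the first year it is
    known to exist); the other three bounds may be absent.  Destruction
    bounds are both-present or both-absent.
    """

    construction_upper: dt.date
    construction_lower: dt.date | None = None
    destruction_lower: dt.date | None = None
    destruction_upper: dt.date | None = None

    def __post_init__(self) -> None:
        cl, cu = self.construction_lower, self.construction_upper
        dl, du = self.destruction_lower, self.destruction_upper
        if (dl is None) != (du is None):
            raise ValueError("destruction bounds must be both present or both absent")
        if cl is not None and not cl < cu:
            raise ValueError(f"construction_lower {cl} must precede upper {cu}")
        if dl is not None and not dl < du:
            raise ValueError(f"destruction_lower {dl} must precede upper {du}")
        if dl is not None and not cu <= dl:
            raise ValueError("facility must be built before it is destroyed")


def bounds_from_yearly_observations(
    observations: Mapping[int, Observation | str],
) -> DateBounds:
    """Derive lifetime bounds from a year -> presence map.

    The construction upper bound is the last day of the first year the
    facility appears (it existed by then); the construction lower bound is
    the first day of the latest preceding year in which the site was
    observed without it.  Symmetrically, the destruction lower bound is the
    last day of the final year the facility appears and the destruction
    upper bound the first day of the earliest later year it is absent.
    Years with no usable image are ignored.
    """
    obs = {int(y): Observation(v) for y, v in observations.items()}
    present = sorted(y for y, v in obs.items() if v is Observation.PRESENT)
    absent = sorted(y for y, v in obs.items() if v is Observation.ABSENT)
    if not present:
        raise ValueError("no year with the facility present; cannot bound lifetime")

    first_seen, last_seen = present[0], present[-1]
    before = [y for y in absent if y < first_seen]
    after = [y for y in absent if y > last_seen]

    construction_lower = dt.date(max(before), 1, 1) if before else None
    construction_upper = dt.date(first_seen, 12, 31)
    if after:
        destruction_lower = dt.date(last_seen, 12, 31)
        destruction_upper = dt.date(min(after), 1, 1)
    else:
        destruction_lower = destruction_upper = None
    return DateBounds(
        construction_upper=construction_upper,
        construction_lower=construction_lower,
        destruction_lower=destruction_lower,
        destruction_upper=destruction_upper,
    )


def classify_lifetime_profile(bounds: DateBounds) -> LifetimeProfile:
    """Classify a facility by which lifetime bounds it carries.

    A facility "has construction bounds" when its construction lower bound
    is known (it was seen absent before it appeared); all facilities have
    the upper bound, so the upper bound alone does not count.
    """
    has_construction = bounds.construction_lower is not None
    has_destruction = bounds.destruction_lower is not None
    if has_construction and has_destruction:
        return LifetimeProfile.BOTH
    if has_construction:
        return LifetimeProfile.CONSTRUCTION_ONLY
    if has_destruction:
        return LifetimeProfile.DESTRUCTION_ONLY
    return LifetimeProfile.NEITHER


@dataclass(frozen=True)
class AnimalTypeLabel:
    """A resolved animal-type annotation with its provenance."""

    types: frozenset[str]
    source: str  # "permit" | "human"

    def __post_init__(self) -> None:
        unknown = set(self.types) - ANIMAL_TYPES
        if unknown:
            raise ValueError(f"unrecognized animal types: {sorted(unknown)}")
        if self.source not in ("permit", "human"):
            raise ValueError(f"source must be 'permit' or 'human', got {self.source!r}")
        if "dairy" in self.types and "cattle" not in self.types:
            raise ValueError("dairy facilities are a subset of cattle facilities")
        if "unknown" in self.types and len(self.types) > 1:
            raise ValueError("'unknown' cannot combine with other types")
        if not self.types:
            raise ValueError("label must carry at least one type")


def resolve_animal_type(
    best_permit_programs: Sequence[str],
    human_label: set[str] | frozenset[str] | None = None,
) -> AnimalTypeLabel:
    """Resolve a facility's animal type from permits, else human annotation.

    If the facility's best-matched permits exist and are all cattle-program
    permits, it is typed ``{cattle}`` from the permit register.  Otherwise a
    human label is required; a human label of ``dairy`` implies ``cattle``,
    and an empty or explicitly unknown human label yields ``{unknown}``.

    Parameters
    ----------
    best_permit_programs : sequence of str
        Regulatory-program strings of the facility's best permit matches;
        a cattle permit is any program containing ``"cattle"`` (the state
        register distinguishes only cattle vs "other" animals).
    human_label : set of str, optional
        Types recorded by a human annotator, if any.

    Raises
    ------
    ValueError
        If permits are inconclusive and no human label is supplied.
    """
    programs = [p.casefold() for p in best_permit_programs]
    if programs and all("cattle" in p for p in programs):
        return AnimalTypeLabel(types=frozenset({"cattle"}), source="permit")
    if human_label is None:
        raise ValueError(
            "permit evidence inconclusive; facility requires human animal typing"
        )
    types = {t.casefold() for t in human_label}
    if not types or types == {"unknown"}:
        return AnimalTypeLabel(types=frozenset({"unknown"}), source="human")
    if "dairy" in types:
        types.add("cattle")
    return AnimalTypeLabel(types=frozenset(types), source="human")


@dataclass(frozen=True)
class LabelDecision:
    annotator_id: str
    item_id: str
    is_cafo: bool


def cohens_kappa(
    decisions_a: Sequence[LabelDecision], decisions_b: Sequence[LabelDecision]
) -> float:
    """Cohen's kappa between two raters over a shared item set.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement rate
    and p_e the agreement expected by chance from the raters' marginal
    label frequencies.  When p_e = 1 (both raters degenerate on the same
    label) kappa is defined as 1.0 if agreement is perfect, otherwise the
    statistic is undefined and an error is raised.
    """
    a = {d.item_id: d.is_cafo for d in decisions_a}
    b = {d.item_id: d.is_cafo for d in decisions_b}
    if len(a) != len(decisions_a) or len(b) != len(decisions_b):
        raise ValueError("duplicate decisions for an (annotator, item) pair")
    if set(a) != set(b):
        raise ValueError("raters must label the same item set")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two items")
    items = sorted(a)
    va = [a[i] for i in items]
    vb = [b[i] for i in items]
    p_o = sum(x == y for x, y in zip(va, vb)) / n
    pa_pos = sum(va) / n
    pb_pos = sum(vb) / n
    p_e = pa_pos * pb_pos + (1 - pa_pos) * (1 - pb_pos)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("degenerate marginals with imperfect agreement")
    return (p_o - p_e) / (1 - p_e)


@dataclass
class ReviewOutcome:
    """Per-stage confirmation flags for the three-way review filter."""

    initial_label_cafo: bool
    typing_stage_cafo: bool
    dating_stage_cafo: bool

    @property
    def confirmed(self) -> bool:
        return (
            self.initial_label_cafo
            and self.typing_stage_cafo
            and self.dating_stage_cafo
        )


def review_attrition_shares(
    n_clustered: int, n_removed_dating: int, n_removed_typing: int
) -> dict[str, float]:
    """Percent of initially clustered facilities removed at each review stage.

    Returns percentages (0-100) rounded to two decimals.
    """
    if n_clustered <= 0:
        raise ValueError("need a positive clustered-facility count")
    return {
        "removed_dating_pct": round(100.0 * n_removed_dating / n_clustered, 2),
        "removed_typing_pct": round(100.0 * n_removed_typing / n_clustered, 2),
    }
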
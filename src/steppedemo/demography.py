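"""Two-deme demographic scenarios for extrazonal/zonal steppe lineages.

Three explicit hypotheses about late-Quaternary population-size dynamics are
modelled for a pair of sister lineages, one restricted to extrazonal steppe
patches (EZ) and one from the continuous zonal steppe (Z):

* ``PARALLEL_EXPANSION`` — both lineages expand during the last glacial
  period (LGP) and contract again in the Holocene.
* ``ZONAL_ONLY`` — only the zonal lineage expands and contracts; the
  extrazonal lineage keeps a constant size.
* ``NO_EXPANSION`` — neither lineage changes size.

All scenarios share a three-epoch history bounded (backward in time) by the
Holocene contraction time ``t_contr``, the LGP expansion time ``t_exp`` and
the initial split ``t_split``, with bidirectional migration between the two
demes in the pre-LGP and LGP epochs only.  Sizes are diploid effective
population sizes; migration rates are per-generation migrant fractions in
forward time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ScenarioId",
    "DemographyParams",
    "PriorSpec",
    "PriorSet",
    "PriorError",
    "default_priors",
    "draw_parameters",
    "validate_params",
    "event_schedule",
    "DemographicEvent",
    "EventSchedule",
    "fold_change",
]


class ScenarioId(enum.IntEnum):
    """The three demographic scenarios, with stable integer codes for CNN labels."""

    PARALLEL_EXPANSION = 0
    ZONAL_ONLY = 1
    NO_EXPANSION = 2

    @property
    def ez_expands(self) -> bool:
        return self is ScenarioId.PARALLEL_EXPANSION

    @property
    def z_expands(self) -> bool:
        return self is not ScenarioId.NO_EXPANSION


# Parameter names that are drawn from priors (scenario constraints are applied
# afterwards by copying, never by re-drawing the constrained field).
SIZE_PARAMS = ("n_anc", "n_ez_pre", "n_z_pre", "n_ez_lgp", "n_z_lgp", "n_ez_post", "n_z_post")
TIME_PARAMS = ("t_split_years", "t_exp_years", "t_contr_years")
MIGRATION_PARAMS = ("m_ez_to_z_pre", "m_z_to_ez_pre", "m_ez_to_z_lgp", "m_z_to_ez_lgp")
FREE_PARAMS = TIME_PARAMS + SIZE_PARAMS + MIGRATION_PARAMS


@dataclass(frozen=True)
class DemographyParams:
    """One complete draw of scenario parameters.

    Times are years before present; sizes are diploid effective sizes; the
    ``m_*`` fields are forward-time per-generation migrant fractions (the
    proportion of the receiving deme replaced by migrants each generation).
    There is no migration in the post-contraction (Holocene) epoch.
    """

    scenario: ScenarioId
    t_split_years: float
    t_exp_years: float
    t_contr_years: float
    n_anc: float
    n_ez_pre: float
    n_z_pre: float
    n_ez_lgp: float
    n_z_lgp: float
    n_ez_post: float
    n_z_post: float
    m_ez_to_z_pre: float
    m_z_to_ez_pre: float
    m_ez_to_z_lgp: float
    m_z_to_ez_lgp: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class PriorSpec:
    """A one-dimensional prior: uniform or log-uniform on [low, high)."""

    name: str
    family: str  # "uniform" | "log-uniform"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "log-uniform"):
            raise PriorError(f"unknown prior family {self.family!r} for {self.name}")
        if not self.low < self.high:
            raise PriorError(f"prior for {self.name} requires low < high")
        if self.family == "log-uniform" and self.low <= 0:
            raise PriorError(f"log-uniform prior for {self.name} requires low > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))


class PriorError(ValueError):
    """Configuration problem in a prior set."""


@dataclass
class PriorSet:
    """Named priors for every free parameter of the demographic model."""

    specs: dict[str, PriorSpec] = field(default_factory=dict)

    def __getitem__(self, name: str) -> PriorSpec:
        try:
            return self.specs[name]
        except KeyError:
            raise PriorError(f"PriorSet is missing a prior for parameter {name!r}") from None

    def require_complete(self) -> None:
        for name in FREE_PARAMS:
            self[name]

    @classmethod
    def from_dict(cls, d: dict[str, dict]) -> "PriorSet":
        specs = {
            name: PriorSpec(name=name, family=s["family"], low=float(s["low"]), high=float(s["high"]))
            for name, s in d.items()
        }
        return cls(specs=specs)

    def to_dict(self) -> dict[str, dict]:
        return {
            n: {"family": s.family, "low": s.low, "high": s.high} for n, s in self.specs.items()
        }


def default_priors() -> PriorSet:
    """Default prior set.

    Interglacial (pre-LGP, Holocene) and ancestral sizes are log-uniform on
    [1e3, 1e5] diploids while LGP sizes are log-uniform on [1e3, 1e7]: under
    the expansion-ordering constraint this spans the tens-of-fold glacial
    expansions the study system shows, while keeping the interglacial epochs
    short enough in coalescent time for the epoch structure to register in
    the data.  The split time is uniform on [300 ky, 1.6 My], the LGP
    expansion time uniform on [30 ky, 115 ky] (the span of the last glacial
    period), and the Holocene contraction time uniform on [1 ky, 12 ky].
    Migrant fractions are log-uniform on [1e-8, 1e-4] per generation: with
    the size priors above this keeps 4*N*m around or below one for typical
    draws, i.e. gene flow restricted enough for two lineages to remain
    distinct over the mid-Pleistocene divergence the system shows, while
    still reaching tens of migrants per generation in the upper tail.
    """
    specs = {}
    for name in SIZE_PARAMS:
        specs[name] = PriorSpec(name, "log-uniform", 1e3, 1e5)
    for name in ("n_ez_lgp", "n_z_lgp"):
        specs[name] = PriorSpec(name, "log-uniform", 1e3, 1e7)
    specs["t_split_years"] = PriorSpec("t_split_years", "uniform", 3.0e5, 1.6e6)
    specs["t_exp_years"] = PriorSpec("t_exp_years", "uniform", 3.0e4, 1.15e5)
    specs["t_contr_years"] = PriorSpec("t_contr_years", "uniform", 1.0e3, 1.2e4)
    for name in MIGRATION_PARAMS:
        specs[name] = PriorSpec(name, "log-uniform", 1e-8, 1e-4)
    return PriorSet(specs=specs)


_MAX_REJECTION_ATTEMPTS = 1000


def draw_parameters(priors: PriorSet, scenario: ScenarioId, seed: int) -> DemographyParams:
    """Draw one parameter set from the priors under a scenario.

    Time ordering (t_contr < t_exp < t_split) and, in expanding lineages, the
    size ordering n_lgp > max(n_pre, n_post) that defines an LGP expansion,
    are enforced by rejection re-sampling; scenario equality constraints are
    applied by copying the constrained fields after drawing.
    """
    priors.require_complete()
    if seed < 0:
        raise ValueError("seed must be >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        draw = {name: priors[name].sample(rng) for name in FREE_PARAMS}
        # scenario equality constraints: copy, never re-draw
        if not scenario.ez_expands:
            draw["n_ez_lgp"] = draw["n_ez_pre"]
            draw["n_ez_post"] = draw["n_ez_pre"]
        if not scenario.z_expands:
            draw["n_z_lgp"] = draw["n_z_pre"]
            draw["n_z_post"] = draw["n_z_pre"]
        params = DemographyParams(scenario=scenario, **draw)
        if not validate_params(params):
            return params
    raise PriorError(
        f"could not draw admissible parameters for {scenario.name} in "
        f"{_MAX_REJECTION_ATTEMPTS} attempts; check prior bounds"
    )


def validate_params(params: DemographyParams) -> list[str]:
    """Return human-readable descriptions of every violated invariant (empty if valid)."""
    v: list[str] = []
    p = params
    if not 0 < p.t_contr_years < p.t_exp_years < p.t_split_years:
        v.append(
            "time ordering: requires 0 < t_contr_years < t_exp_years < t_split_years, got "
            f"({p.t_contr_years}, {p.t_exp_years}, {p.t_split_years})"
        )
    for name in SIZE_PARAMS:
        if not getattr(p, name) > 0:
            v.append(f"{name}: population sizes must be > 0")
    for name in MIGRATION_PARAMS:
        m = getattr(p, name)
        if not 0 <= m <= 0.5:
            v.append(f"{name}: migrant fraction must be in [0, 0.5]")
    scen = p.scenario
    if not scen.ez_expands:
        if not (p.n_ez_pre == p.n_ez_lgp == p.n_ez_post):
            v.append(
                f"scenario {scen.name}: extrazonal sizes must be constant "
                "(n_ez_pre == n_ez_lgp == n_ez_post)"
            )
    elif not (p.n_ez_lgp > p.n_ez_pre and p.n_ez_lgp > p.n_ez_post):
        v.append(
            f"scenario {scen.name}: extrazonal LGP expansion requires "
            "n_ez_lgp > max(n_ez_pre, n_ez_post)"
        )
    if not scen.z_expands:
        if not (p.n_z_pre == p.n_z_lgp == p.n_z_post):
            v.append(
                f"scenario {scen.name}: zonal sizes must be constant "
                "(n_z_pre == n_z_lgp == n_z_post)"
            )
    elif not (p.n_z_lgp > p.n_z_pre and p.n_z_lgp > p.n_z_post):
        v.append(
            f"scenario {scen.name}: zonal LGP expansion requires "
            "n_z_lgp > max(n_z_pre, n_z_post)"
        )
    return v


@dataclass(frozen=True)
class DemographicEvent:
    """A backward-time state change at ``time_gen`` generations before present.

    ``kind`` is one of "contraction_boundary" (Holocene sizes -> LGP sizes,
    migration switches on at LGP rates), "expansion_boundary" (LGP sizes ->
    pre-LGP sizes and migration rates) or "split" (the two demes merge into
    the ancestral deme; migration off).  Sizes/migration describe the state
    OLDER than the event; ``None`` entries at the split mean the deme no
    longer exists.
    """

    time_gen: float
    kind: str
    size_ez: float | None
    size_z: float | None
    size_anc: float | None
    m_ez_to_z: float
    m_z_to_ez: float


@dataclass(frozen=True)
class EventSchedule:
    """Present-day state plus the ordered (ascending backward-time) event list."""

    size_ez_present: float
    size_z_present: float
    events: tuple[DemographicEvent, ...]

    def epoch_sizes(self) -> dict[str, float]:
        """Reconstruct the seven epoch sizes from the schedule (round-trip check)."""
        contr, exp, split = self.events
        return {
            "n_ez_post": self.size_ez_present,
            "n_z_post": self.size_z_present,
            "n_ez_lgp": contr.size_ez,
            "n_z_lgp": contr.size_z,
            "n_ez_pre": exp.size_ez,
            "n_z_pre": exp.size_z,
            "n_anc": split.size_anc,
        }


def event_schedule(params: DemographyParams, gen_time_years: float) -> EventSchedule:
    """Translate a parameter draw into a backward-time event schedule.

    Event times are years / gen_time_years (kept exact so the schedule is
    linear in 1/gen_time).  Epoch sizes are piecewise constant; migration is
    zero in the Holocene epoch, at LGP rates between t_contr and t_exp, and
    at pre-LGP rates between t_exp and t_split.
    """
    if not gen_time_years > 0:
        raise ValueError("gen_time_years must be > 0")
    bad = validate_params(params)
    if bad:
        raise ValueError("invalid params: " + "; ".join(bad))
    g = float(gen_time_years)
    p = params
    events = (
        DemographicEvent(
            time_gen=p.t_contr_years / g,
            kind="contraction_boundary",
            size_ez=p.n_ez_lgp,
            size_z=p.n_z_lgp,
            size_anc=None,
            m_ez_to_z=p.m_ez_to_z_lgp,
            m_z_to_ez=p.m_z_to_ez_lgp,
        ),
        DemographicEvent(
            time_gen=p.t_exp_years / g,
            kind="expansion_boundary",
            size_ez=p.n_ez_pre,
            size_z=p.n_z_pre,
            size_anc=None,
            m_ez_to_z=p.m_ez_to_z_pre,
            m_z_to_ez=p.m_z_to_ez_pre,
        ),
        DemographicEvent(
            time_gen=p.t_split_years / g,
            kind="split",
            size_ez=None,
            size_z=None,
            size_anc=p.n_anc,
            m_ez_to_z=0.0,
            m_z_to_ez=0.0,
        ),
    )
    return EventSchedule(size_ez_present=p.n_ez_post, size_z_present=p.n_z_post, events=events)


def fold_change(n_from: float, n_to: float) -> float:
    """Fold change n_to / n_from between two effective sizes (both must be > 0)."""
    if not (n_from > 0 and n_to > 0):
        raise ValueError("fold_change requires positive sizes")
    return n_to / n_from
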
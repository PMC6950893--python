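"""Three-tier summary food web and gLV parameter sign constraints.

Prior knowledge enters the inference as a trophic-index table (FishBase
convention: one plus the weighted mean trophic level of the food items) plus a
list of literature-documented predator-prey pairs.  Species are classified
into a three-tier web (resource prey, meso predator, top predator) compatible
with both priors, all potential interactions are summarized by simple
ecological rules, and the interaction classes are converted into sign
restrictions on the gLV coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import SignConstraintSet

TIERS = ("resource_prey", "meso_predator", "top_predator")
_TIER_RANK = {t: k for k, t in enumerate(TIERS)}


class InfeasibleFoodWebError(ValueError):
    """No three-tier assignment satisfies the trophic priors."""

    def __init__(self, message: str, violating_pairs=()):
        super().__init__(message)
        self.violating_pairs = list(violating_pairs)


@dataclass(frozen=True)
class TrophicPrior:
    """Per-species trophic index and known predator-prey pairs."""

    trophic_index: dict[str, float]
    known_predation: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "trophic_index", {str(k): float(v) for k, v in self.trophic_index.items()}
        )
        pairs = tuple((str(p), str(q)) for p, q in self.known_predation)
        species = set(self.trophic_index)
        for idx_val in self.trophic_index.values():
            if idx_val <= 1.0:
                raise ValueError("trophic indices must exceed 1")
        for pred, prey in pairs:
            if pred == prey:
                raise ValueError(f"self-predation pair ({pred}, {prey})")
            if pred not in species or prey not in species:
                raise ValueError(f"predation pair ({pred}, {prey}) references unknown species")
        object.__setattr__(self, "known_predation", pairs)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(self.trophic_index)

    @classmethod
    def from_config(cls, path: str | Path) -> "TrophicPrior":
        """Load from a JSON or YAML config with keys ``trophic_index`` and
        ``known_predation`` (list of [predator, prey] pairs)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(
            trophic_index=data["trophic_index"],
            known_predation=tuple(tuple(p) for p in data.get("known_predation", [])),
        )


@dataclass(frozen=True)
class TrophicAssignment:
    """Tier (resource_prey / meso_predator / top_predator) per species."""

    tiers: dict[str, str]

    def __post_init__(self) -> None:
        for sp, tier in self.tiers.items():
            if tier not in TIERS:
                raise ValueError(f"unknown tier {tier!r} for species {sp!r}")

    def rank(self, species: str) -> int:
        return _TIER_RANK[self.tiers[species]]

    def species_in(self, tier: str) -> tuple[str, ...]:
        return tuple(s for s, t in self.tiers.items() if t == tier)


@dataclass(frozen=True)
class SummaryFoodWeb:
    """All potential interactions among the community's species.

    ``interactions`` maps each unordered pair (stored as a sorted tuple) to
    either ``("predation", predator, prey)``, ``("competition",)`` or
    ``("none",)``.  Every species additionally self-limits (intraspecific
    competition), and its growth-rate sign is set by its tier.
    """

    species_ids: tuple[str, ...]
    tiers: dict[str, str]
    interactions: dict[tuple[str, str], tuple] = field(default_factory=dict)

    def interaction(self, a: str, b: str) -> tuple:
        return self.interactions[tuple(sorted((a, b)))]


def _satisfies(prior: TrophicPrior, tiers: dict[str, str]) -> list[tuple[str, str]]:
    """Return the list of violated constraints (empty when feasible)."""
    bad = []
    idx = prior.trophic_index
    # (a) index ordering between tiers
    for a in idx:
        for b in idx:
            if _TIER_RANK[tiers[a]] > _TIER_RANK[tiers[b]] and idx[a] < idx[b]:
                bad.append((a, b))
    # (b) known predators strictly above their prey
    for pred, prey in prior.known_predation:
        if _TIER_RANK[tiers[pred]] <= _TIER_RANK[tiers[prey]]:
            bad.append((pred, prey))
    return bad


def _sorted_species(prior: TrophicPrior) -> list[str]:
    """Ascending trophic index; ties broken so known prey precede predators."""
    species = sorted(prior.trophic_index, key=lambda s: (prior.trophic_index[s], s))
    # local topological pass inside tie groups
    i = 0
    while i < len(species):
        j = i
        while j < len(species) and prior.trophic_index[species[j]] == prior.trophic_index[species[i]]:
            j += 1
        group = species[i:j]
        if len(group) > 1:
            pairs = [(p, q) for p, q in prior.known_predation if p in group and q in group]
            if pairs:
                group = _topo_sort(group, pairs)
                species[i:j] = group
        i = j
    return species


def _topo_sort(group: list[str], pairs: list[tuple[str, str]]) -> list[str]:
    """Order so every prey comes before its predator (Kahn's algorithm)."""
    out: list[str] = []
    remaining = list(group)
    while remaining:
        # a species whose prey (within the remaining set) are all placed
        ready = [s for s in remaining
                 if not any(p == s and q in remaining for p, q in pairs)]
        pick = sorted(ready or remaining)[0]  # cycles fall back to name order
        out.append(pick)
        remaining.remove(pick)
    return out


def classify_trophic_levels(prior: TrophicPrior) -> TrophicAssignment:
    """Assign each species to one of three tiers compatible with the priors.

    Constraints: every species in a higher tier has trophic index >= every
    species in any lower tier, and every known predator sits strictly above
    its prey.  Among feasible assignments the deterministic tie-break keeps
    species as low in the web as possible (largest resource-prey tier, then
    largest meso tier), consistent with the index ranking.
    """
    if not prior.trophic_index:
        raise ValueError("prior must contain at least one species")
    order = _sorted_species(prior)
    n = len(order)
    best: dict[str, str] | None = None
    # tiers are contiguous blocks of the index-sorted order: prey = order[:c1],
    # meso = order[c1:c2], top = order[c2:]; prefer large c1, then large c2
    for c1 in range(n, -1, -1):
        for c2 in range(n, c1 - 1, -1):
            tiers = {}
            for k, sp in enumerate(order):
                tiers[sp] = TIERS[0] if k < c1 else (TIERS[1] if k < c2 else TIERS[2])
            if not _satisfies(prior, tiers):
                best = tiers
                break
        if best is not None:
            break
    if best is None:
        # report violations of the most permissive ordering attempt
        fallback = {sp: TIERS[0] for sp in order}
        raise InfeasibleFoodWebError(
            "no three-tier assignment satisfies the trophic priors",
            violating_pairs=_satisfies(prior, fallback),
        )
    return TrophicAssignment(tiers=best)


def build_summary_web(assignment: TrophicAssignment, prior: TrophicPrior) -> SummaryFoodWeb:
    """Summarize all potential interactions from tiers and known predation.

    Adjacent-tier pairs become predation (higher tier eats the immediately
    lower one); known predator-prey pairs become predation at any tier gap;
    same-tier pairs compete; every species self-limits; remaining pairs are
    non-interacting.
    """
    species = tuple(prior.species_ids)
    missing = [s for s in species if s not in assignment.tiers]
    if missing:
        raise ValueError(f"assignment does not cover species {missing}")
    known = {}
    for pred, prey in prior.known_predation:
        if assignment.rank(pred) == assignment.rank(prey):
            raise InfeasibleFoodWebError(
                f"known predation ({pred}, {prey}) within a single tier",
                violating_pairs=[(pred, prey)],
            )
        known[tuple(sorted((pred, prey)))] = (pred, prey)
    interactions: dict[tuple[str, str], tuple] = {}
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            key = tuple(sorted((a, b)))
            ra, rb = assignment.rank(a), assignment.rank(b)
            if key in known:
                pred, prey = known[key]
                interactions[key] = ("predation", pred, prey)
            elif abs(ra - rb) == 1:
                pred, prey = (a, b) if ra > rb else (b, a)
                interactions[key] = ("predation", pred, prey)
            elif ra == rb:
                interactions[key] = ("competition",)
            else:
                interactions[key] = ("none",)
    return SummaryFoodWeb(
        species_ids=species, tiers=dict(assignment.tiers), interactions=interactions
    )


def derive_sign_constraints(
    web: SummaryFoodWeb, exogenous_id: str | None = None
) -> SignConstraintSet:
    """Convert a summary food web into gLV sign constraints.

    Predation (j eats i): beta[i, j] negative, beta[j, i] positive.
    Intraspecific competition: diagonal negative.  Interspecific competition:
    both off-diagonal entries negative.  Non-interacting: both zero.  Growth
    rates are positive for the lowest tier and negative above it.  When
    ``exogenous_id`` names a web species, that species is removed from the
    endogenous network and its interactions become per-species susceptibility
    signs instead.
    """
    species = [s for s in web.species_ids if s != exogenous_id]
    if exogenous_id is not None and exogenous_id not in web.species_ids:
        raise ValueError(f"exogenous species {exogenous_id!r} not in web")
    n = len(species)
    beta_sign = np.full((n, n), "zero", dtype=object)
    alpha_sign = np.empty(n, dtype=object)
    for i, sp in enumerate(species):
        beta_sign[i, i] = "negative"  # intraspecific competition, always
        alpha_sign[i] = "positive" if web.tiers[sp] == TIERS[0] else "negative"
    for i, a in enumerate(species):
        for j in range(i + 1, n):
            b = species[j]
            kind = web.interaction(a, b)
            if kind[0] == "predation":
                pred, prey = kind[1], kind[2]
                pi, qi = species.index(pred), species.index(prey)
                beta_sign[qi, pi] = "negative"  # predator hurts prey
                beta_sign[pi, qi] = "positive"  # prey feeds predator
            elif kind[0] == "competition":
                beta_sign[i, j] = "negative"
                beta_sign[j, i] = "negative"
            # "none" stays zero
    epsilon_sign = None
    if exogenous_id is not None:
        epsilon_sign = np.full(n, "zero", dtype=object)
        for i, sp in enumerate(species):
            kind = web.interaction(sp, exogenous_id)
            if kind[0] == "predation":
                # effect of the exogenous species on sp
                epsilon_sign[i] = "positive" if kind[1] == sp else "negative"
            elif kind[0] == "competition":
                epsilon_sign[i] = "negative"
    return SignConstraintSet(
        alpha_sign=alpha_sign,
        beta_sign=beta_sign,
        epsilon_sign=epsilon_sign,
        species_ids=tuple(species),
    )
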
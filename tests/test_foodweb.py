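"""Trophic classification, summary-web rules and sign conversion.

The ten-species river fixture below is a synthetic stand-in: trophic indices
are plausible FishBase-style values assembled for testing, while the known
predator-prey pairs are the literature-documented ones for this community.
"""

import itertools

import numpy as np
import pytest

from glvnet import (
    InfeasibleFoodWebError, TrophicPrior,
    build_summary_web, classify_trophic_levels, derive_sign_constraints,
)
from glvnet.foodweb import TIERS, TrophicAssignment

RIVER_INDEX = {
    "CNCF": 4.0, "WTBS": 3.9, "BKCP": 3.6, "FWDM": 3.4, "BLGL": 3.2,
    "CARP": 3.1, "ERSN": 3.0, "SMBF": 2.8, "GZSD": 2.6, "SVCP": 2.2,
}
RIVER_PREDATION = (
    ("BKCP", "BLGL"), ("CNCF", "BLGL"), ("CNCF", "ERSN"), ("CNCF", "GZSD"),
    ("FWDM", "GZSD"), ("WTBS", "BKCP"), ("WTBS", "BLGL"), ("WTBS", "FWDM"),
    ("WTBS", "ERSN"), ("WTBS", "GZSD"), ("WTBS", "CARP"), ("WTBS", "SVCP"),
)


@pytest.fixture(scope="module")
def river_prior():
    return TrophicPrior(trophic_index=RIVER_INDEX, known_predation=RIVER_PREDATION)


def brute_force_assignments(prior):
    """All 3^N tier assignments satisfying both classification constraints."""
    species = list(prior.trophic_index)
    feasible = []
    for combo in itertools.product(range(3), repeat=len(species)):
        tiers = dict(zip(species, combo))
        ok = all(
            not (tiers[a] > tiers[b] and prior.trophic_index[a] < prior.trophic_index[b])
            for a in species for b in species
        ) and all(tiers[p] > tiers[q] for p, q in prior.known_predation)
        if ok:
            feasible.append({s: TIERS[t] for s, t in tiers.items()})
    return feasible


class TestClassification:
    def test_river_community_tiers(self, river_prior):
        """Catfish and white bass on top; drum and crappie mid; 6 prey."""
        assignment = classify_trophic_levels(river_prior)
        assert assignment.species_in("top_predator") == ("CNCF", "WTBS") or \
            set(assignment.species_in("top_predator")) == {"CNCF", "WTBS"}
        assert set(assignment.species_in("meso_predator")) == {"FWDM", "BKCP"}
        assert len(assignment.species_in("resource_prey")) == 6

    def test_single_species_defaults_to_prey(self):
        prior = TrophicPrior(trophic_index={"only": 2.5})
        assert classify_trophic_levels(prior).tiers == {"only": "resource_prey"}

    def test_three_species_chain_one_per_tier(self):
        prior = TrophicPrior(
            trophic_index={"low": 2.0, "mid": 2.5, "high": 3.0},
            known_predation=(("high", "mid"), ("mid", "low")),
        )
        got = classify_trophic_levels(prior).tiers
        feasible = brute_force_assignments(prior)
        assert feasible == [got]  # the chain forces a unique assignment
        assert got == {"low": "resource_prey", "mid": "meso_predator",
                       "high": "top_predator"}

    def test_matches_brute_force_on_random_priors(self):
        """Exhaustive oracle on small random priors: the returned assignment
        is feasible, and infeasibility is reported iff no assignment exists."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 6))
            names = [f"s{i}" for i in range(n)]
            index = {s: float(rng.uniform(1.5, 4.0)) for s in names}
            pairs = []
            for a, b in itertools.combinations(names, 2):
                if rng.random() < 0.25:
                    pred, prey = (a, b) if index[a] >= index[b] else (b, a)
                    pairs.append((pred, prey))
            prior = TrophicPrior(trophic_index=index, known_predation=tuple(pairs))
            feasible = brute_force_assignments(prior)
            if feasible:
                got = classify_trophic_levels(prior).tiers
                assert got in feasible
            else:
                with pytest.raises(InfeasibleFoodWebError):
                    classify_trophic_levels(prior)

    def test_predation_cycle_reported(self):
        prior = TrophicPrior(
            trophic_index={"a": 2.0, "b": 2.0},
            known_predation=(("a", "b"), ("b", "a")),
        )
        with pytest.raises(InfeasibleFoodWebError) as err:
            classify_trophic_levels(prior)
        assert err.value.violating_pairs


class TestSummaryWeb:
    def test_river_web_contains_documented_predation(self, river_prior):
        assignment = classify_trophic_levels(river_prior)
        web = build_summary_web(assignment, river_prior)
        assert web.interaction("WTBS", "GZSD") == ("predation", "WTBS", "GZSD")
        assert web.interaction("CNCF", "ERSN") == ("predation", "CNCF", "ERSN")

    def test_same_tier_pair_competes(self):
        prior = TrophicPrior(trophic_index={"a": 2.0, "b": 2.1})
        web = build_summary_web(classify_trophic_levels(prior), prior)
        assert web.interaction("a", "b") == ("competition",)

    def test_three_tiers_adjacent_predation_distant_none(self):
        prior = TrophicPrior(
            trophic_index={"low": 2.0, "mid": 2.5, "high": 3.0},
            known_predation=(("high", "mid"), ("mid", "low")),
        )
        assignment = classify_trophic_levels(prior)
        # drop the known pairs: rule 1 alone must give adjacent-tier predation
        bare = TrophicPrior(trophic_index=prior.trophic_index)
        web = build_summary_web(assignment, bare)
        assert web.interaction("high", "mid") == ("predation", "high", "mid")
        assert web.interaction("mid", "low") == ("predation", "mid", "low")
        assert web.interaction("high", "low") == ("none",)

    def test_known_pair_within_one_tier_rejected(self):
        prior = TrophicPrior(
            trophic_index={"a": 2.0, "b": 2.0}, known_predation=(("a", "b"),),
        )
        assignment = TrophicAssignment(
            tiers={"a": "resource_prey", "b": "resource_prey"}
        )
        with pytest.raises(InfeasibleFoodWebError):
            build_summary_web(assignment, prior)


class TestSignConversion:
    def chain_constraints(self):
        prior = TrophicPrior(
            trophic_index={"low": 2.0, "mid": 2.5, "high": 3.0},
            known_predation=(("high", "mid"), ("mid", "low")),
        )
        web = build_summary_web(classify_trophic_levels(prior), prior)
        return derive_sign_constraints(web), web

    def test_predation_signs(self):
        cons, _ = self.chain_constraints()
        ids = list(cons.species_ids)
        low, mid, high = ids.index("low"), ids.index("mid"), ids.index("high")
        assert cons.beta_sign[low, mid] == "negative"   # predator hurts prey
        assert cons.beta_sign[mid, low] == "positive"   # prey feeds predator
        assert cons.beta_sign[low, high] == "zero"      # non-interacting pair
        assert cons.beta_sign[high, low] == "zero"

    def test_diagonal_always_negative(self):
        cons, _ = self.chain_constraints()
        assert all(cons.beta_sign[i, i] == "negative" for i in range(3))

    def test_growth_signs_by_tier(self):
        cons, _ = self.chain_constraints()
        ids = list(cons.species_ids)
        assert cons.alpha_sign[ids.index("low")] == "positive"
        assert cons.alpha_sign[ids.index("mid")] == "negative"
        assert cons.alpha_sign[ids.index("high")] == "negative"

    def test_pure_competition_community(self):
        prior = TrophicPrior(trophic_index={c: 2.0 + 0.01 * i
                                            for i, c in enumerate("abcd")})
        web = build_summary_web(classify_trophic_levels(prior), prior)
        cons = derive_sign_constraints(web)
        assert (cons.beta_sign == "negative").all()
        assert (cons.alpha_sign == "positive").all()

    def test_exogenous_species_maps_to_epsilon(self, river_prior):
        assignment = classify_trophic_levels(river_prior)
        web = build_summary_web(assignment, river_prior)
        cons = derive_sign_constraints(web, exogenous_id="SVCP")
        assert cons.n_species == 9
        ids = list(cons.species_ids)
        # white bass eats the exogenous species (documented pair): positive
        assert cons.epsilon_sign[ids.index("WTBS")] == "positive"
        # meso predators eat the immediately-lower prey tier it occupies
        assert cons.epsilon_sign[ids.index("FWDM")] == "positive"
        # fellow resource prey compete with it: negative susceptibility
        assert cons.epsilon_sign[ids.index("GZSD")] == "negative"
        # a top predator with no documented pair is two tiers away: no link
        assert cons.epsilon_sign[ids.index("CNCF")] == "zero"
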
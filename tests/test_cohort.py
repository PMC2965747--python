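"""Censoring rules, pedigree kinship, baseline incidence, stratification."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad

from carriermod.cohort import (
    Carrier,
    EventHistory,
    IncidenceModel,
    Pedigree,
    StratumScheme,
    ValidationError,
    assign_strata,
    cumulative_hazard,
    derive_time_at_risk,
    kinship_matrix,
)


class TestDeriveTimeAtRisk:
    @pytest.mark.parametrize(
        "history,expected",
        [
            (dict(breast_dx_age=38, last_obs_age=45), (38, True, "breast")),
            (dict(ovarian_dx_age=45, last_obs_age=60), (45, False, "ovarian")),
            (dict(last_obs_age=85), (80, False, "age_cap")),
            (dict(bpm_age=40, breast_dx_age=43), (40, False, "bpm")),
            # BPM within a year of the cancer does not override it
            (dict(bpm_age=42.5, breast_dx_age=43), (43, True, "breast")),
            (dict(bpm_age=50, last_obs_age=70), (50, False, "bpm")),
            # first cancer wins when ovarian precedes breast
            (dict(ovarian_dx_age=40, breast_dx_age=50, last_obs_age=60), (40, False, "ovarian")),
        ],
    )
    def test_censoring_rules(self, history, expected):
        assert derive_time_at_risk(EventHistory(**history)) == expected

    def test_no_observation_rejected(self):
        with pytest.raises(ValidationError, match="no observation"):
            derive_time_at_risk(EventHistory())

    @pytest.mark.parametrize("bad", [dict(last_obs_age=-3), dict(breast_dx_age=0, last_obs_age=50)])
    def test_nonpositive_ages_rejected(self, bad):
        with pytest.raises(ValidationError):
            derive_time_at_risk(EventHistory(**bad))

    def test_event_postdating_interview_rejected(self):
        with pytest.raises(ValidationError, match="postdates"):
            derive_time_at_risk(EventHistory(breast_dx_age=55, last_obs_age=50))

    def test_idempotent_and_deterministic(self, rng):
        for _ in range(50):
            ages = np.round(rng.uniform(20, 90, size=4), 1)
            h = EventHistory(
                breast_dx_age=ages[0] if rng.random() < 0.5 else None,
                ovarian_dx_age=ages[1] if rng.random() < 0.5 else None,
                bpm_age=ages[2] if rng.random() < 0.5 else None,
                last_obs_age=max(ages),
            )
            assert derive_time_at_risk(h) == derive_time_at_risk(h)


def _kinship_enumeration_oracle(ped: Pedigree, a: str, b: str) -> float:
    """Exhaustive gene-dropping: enumerate every Mendelian transmission.

    Founders carry unique allele labels; every non-founder configuration of
    (paternal pick, maternal pick) is enumerated and phi(a, b) is the
    average probability that one allele sampled from each is identical by
    descent.
    """
    parents = {m[0]: (m[1], m[2]) for m in ped.members}
    order = []
    placed = set()
    while len(order) < len(parents):
        for iid, (f, m) in parents.items():
            if iid in placed:
                continue
            if (f is None or f in placed or f not in parents) and (
                m is None or m in placed or m not in parents
            ):
                order.append(iid)
                placed.add(iid)
    nonfounders = [i for i in order if any(p is not None and p in parents for p in parents[i])]
    label = itertools.count()
    base: dict[str, tuple] = {}
    for i in order:
        f, m = parents[i]
        if not (f in parents or m in parents):
            base[i] = (next(label), next(label))
    total = 0.0
    configs = list(itertools.product([0, 1], repeat=2 * len(nonfounders)))
    for cfg in configs:
        alleles = dict(base)
        for k, i in enumerate(nonfounders):
            f, m = parents[i]
            pat = alleles[f][cfg[2 * k]] if f in parents else (next(label), None)[0]
            mat = alleles[m][cfg[2 * k + 1]] if m in parents else (next(label), None)[0]
            alleles[i] = (pat, mat)
        aa, bb = alleles[a], alleles[b]
        total += np.mean([x == y for x in aa for y in bb])
    return total / len(configs)


PEDIGREES = {
    "trio": Pedigree("f", [("p1", None, None, 1), ("p2", None, None, 2), ("c", "p1", "p2", 2)]),
    "sibs": Pedigree(
        "f",
        [
            ("p1", None, None, 1),
            ("p2", None, None, 2),
            ("s1", "p1", "p2", 2),
            ("s2", "p1", "p2", 2),
        ],
    ),
    "half_sibs": Pedigree(
        "f",
        [
            ("p1", None, None, 1),
            ("p2", None, None, 2),
            ("p3", None, None, 2),
            ("h1", "p1", "p2", 2),
            ("h2", "p1", "p3", 2),
        ],
    ),
    "three_gen": Pedigree(
        "f",
        [
            ("g1", None, None, 1),
            ("g2", None, None, 2),
            ("m", "g1", "g2", 2),
            ("dad", None, None, 1),
            ("k", "dad", "m", 2),
        ],
    ),
    "avuncular": Pedigree(
        "f",
        [
            ("p1", None, None, 1),
            ("p2", None, None, 2),
            ("s1", "p1", "p2", 2),
            ("s2", "p1", "p2", 2),
            ("dad", None, None, 1),
            ("n", "dad", "s1", 2),
        ],
    ),
}


class TestKinship:
    @pytest.mark.parametrize("name", list(PEDIGREES))
    def test_matches_enumeration_oracle(self, name):
        ped = PEDIGREES[name]
        ids = ped.ids()
        km = kinship_matrix(ped, ids)
        for a in ids:
            for b in ids:
                assert km.get(a, b) == pytest.approx(
                    _kinship_enumeration_oracle(ped, a, b), abs=1e-12
                )

    def test_closed_forms(self):
        km = kinship_matrix(PEDIGREES["sibs"], ["p1", "p2", "s1", "s2"])
        assert km.get("p1", "s1") == 0.25  # parent-offspring
        assert km.get("s1", "s2") == 0.25  # full sibs
        assert km.get("s1", "s1") == 0.5
        assert km.get("p1", "p2") == 0.0

    def test_cross_family_founders_unrelated(self):
        p1 = Pedigree("f1", [("a", None, None, 2)])
        p2 = Pedigree("f2", [("b", None, None, 2)])
        km = kinship_matrix([p1, p2], ["a", "b"])
        assert km.get("a", "b") == 0.0

    def test_singletons_not_in_pedigree(self):
        km = kinship_matrix([], ["x", "y"])
        assert km.get("x", "x") == 0.5
        assert km.get("x", "y") == 0.0

    def test_cyclic_pedigree_rejected(self):
        bad = Pedigree("f", [("a", "b", None, 1), ("b", "a", None, 2)])
        with pytest.raises(ValidationError, match="cyclic"):
            kinship_matrix(bad, ["a", "b"])


class TestIncidence:
    def test_single_band(self):
        m = IncidenceModel([0, 50, 80], [0.01, 0.0])
        assert cumulative_hazard(30, None, m) == pytest.approx(0.30)
        assert cumulative_hazard(0, None, m) == 0.0

    def test_outside_range_rejected(self):
        m = IncidenceModel([0, 80], [0.01])
        with pytest.raises(ValidationError):
            cumulative_hazard(81, None, m)
        with pytest.raises(ValidationError):
            cumulative_hazard(-1, None, m)

    def test_matches_quadrature_oracle(self, rng):
        edges = np.concatenate([[0.0], np.sort(rng.uniform(1, 79, 5)), [80.0]])
        rates = rng.uniform(0, 0.05, 6)
        m = IncidenceModel(edges, rates)

        def step(u):
            k = np.searchsorted(edges, u, side="right") - 1
            return rates[min(k, 5)]

        for t in rng.uniform(0, 80, 10):
            val, _ = quad(step, 0, t, limit=200, points=list(edges[edges < t]))
            assert cumulative_hazard(t, None, m) == pytest.approx(val, abs=1e-8)

    def test_monotone_and_scale_equivariant(self, rng):
        m = IncidenceModel([0, 20, 40, 80], [0.001, 0.01, 0.02])
        m2 = IncidenceModel([0, 20, 40, 80], [0.002, 0.02, 0.04])
        ts = np.sort(rng.uniform(0, 80, 20))
        vals = [cumulative_hazard(t, None, m) for t in ts]
        assert np.all(np.diff(vals) >= 0)
        for t in ts:
            assert cumulative_hazard(t, None, m2) == pytest.approx(
                2 * cumulative_hazard(t, None, m)
            )

    def test_cohort_multiplier(self):
        m = IncidenceModel([0, 80], [0.01], cohort_multipliers={1950: 2.0})
        assert cumulative_hazard(10, 1955, m) == pytest.approx(0.2)
        assert cumulative_hazard(10, 1970, m) == pytest.approx(0.1)


def _carrier(i, country, delt, affected=False, fam=None):
    return Carrier(f"i{i}", fam or f"f{i}", country, delt, 45.0, affected)


class TestStrata:
    def test_distinct_keys(self):
        carriers = [_carrier(0, "UK", False), _carrier(1, "UK", True), _carrier(2, "UK", False)]
        keys, summary, excluded = assign_strata(carriers)
        assert keys["i0"] != keys["i1"]
        assert keys["i0"] == keys["i2"]
        assert not excluded

    def test_missing_field_excluded(self):
        carriers = [_carrier(0, None, False), _carrier(1, "UK", False), _carrier(2, "UK", False)]
        keys, _, excluded = assign_strata(carriers)
        assert ("i0", "missing stratum field") in excluded
        assert "i0" not in keys

    def test_relabeling_invariance(self):
        c1 = [_carrier(i, ["UK", "US"][i % 2], False) for i in range(6)]
        c2 = [_carrier(i, ["US", "UK"][i % 2], False) for i in range(6)]
        _, s1, _ = assign_strata(c1)
        _, s2, _ = assign_strata(c2)
        assert sorted(s1["n"]) == sorted(s2["n"])

    def test_small_strata_pooled(self):
        carriers = [_carrier(i, "UK", False) for i in range(5)] + [_carrier(9, "UK", True)]
        keys, _, _ = assign_strata(carriers, StratumScheme(min_carriers=2))
        assert keys["i9"] == "UK|rest"

    def test_stage_appended(self):
        carriers = [_carrier(0, "UK", False), _carrier(1, "UK", False)]
        keys, _, _ = assign_strata(carriers, StratumScheme(include_stage=True))
        assert keys["i0"].endswith("stage=1")

    def test_bounded_stratum_count(self):
        rng = np.random.default_rng(3)
        countries = [f"c{k}" for k in range(14)]
        carriers = [
            _carrier(i, countries[rng.integers(14)], bool(rng.integers(2)))
            for i in range(500)
        ]
        _, summary, _ = assign_strata(carriers, StratumScheme(min_carriers=1))
        assert len(summary) <= 28
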
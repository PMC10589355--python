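"""Point rules, binding-mode similarity, composite score and ranking."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from dualvs.chem import PropertySet
from dualvs.scoring import (
    MetabolismAnnotation,
    RISK_ENDPOINTS,
    RiskAnnotation,
    ScoreComponents,
    VSRecord,
    composite_score,
    lipinski_points,
    metabolism_penalty,
    rank_library,
    similarity_bm,
    tox_points,
)


def props(mw, logp, hba, hbd):
    return PropertySet(mw, logp, hbd=hbd, hba=hba, tpsa=50.0)


def risk(m, te, tu, i):
    return RiskAnnotation(
        "x",
        dict(zip(RISK_ENDPOINTS, (m, te, tu, i))),
    )


class TestSimilarity:
    def test_self_similarity_is_100(self):
        s = {"Phe130", "Ala131"}
        assert similarity_bm(s, s) == 100.0

    def test_disjoint_sets_are_0(self):
        assert similarity_bm({"Phe1"}, {"Leu2", "Met3"}) == 0.0

    def test_empty_control_is_error(self):
        with pytest.raises(ValueError):
            similarity_bm({"Phe1"}, set())

    def test_count_ratio_interpretation_can_exceed_100(self):
        test = {f"R{i}" for i in range(10)}
        control = {"R0", "R1"}
        assert similarity_bm(test, control, interpretation="count_ratio") == 500.0
        assert similarity_bm(test, control) == 100.0

    @given(
        st.frozensets(st.integers(0, 30), max_size=15),
        st.frozensets(st.integers(0, 30), min_size=1, max_size=15),
        st.integers(0, 30),
    )
    @settings(deadline=None)
    def test_monotone_in_shared_residues(self, test, control, extra):
        base = similarity_bm(test, control)
        if extra in control:
            assert similarity_bm(test | {extra}, control) >= base
        else:
            assert similarity_bm(test | {extra}, control) == base


class TestPointRules:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (props(350, 3.0, 6, 2), 40),
            (props(566.05, 5.5, 7, 1), 10),   # only HBA in range
            (props(150, 1.0, 2, 0), 0),
            (props(200, 2.0, 5, 2), 40),      # lower boundaries inclusive
            (props(500, 5.0, 10, 5), 40),     # upper boundaries inclusive
        ],
    )
    def test_lipinski_points(self, p, expected):
        assert lipinski_points(p) == expected

    @pytest.mark.parametrize(
        "levels,expected",
        [
            (("low",) * 4, 80),
            (("high",) * 4, 0),
            (("low", "low", "medium", "high"), 50),
        ],
    )
    def test_tox_points(self, levels, expected):
        assert tox_points(risk(*levels)) == expected

    def test_tox_requires_all_endpoints(self):
        with pytest.raises(ValueError):
            RiskAnnotation("x", {"mutagenicity": "low"})

    @pytest.mark.parametrize(
        "level,expected", [("high", -20), ("medium", -15), ("low", -10)]
    )
    def test_metabolism_penalty(self, level, expected):
        assert metabolism_penalty(MetabolismAnnotation("x", level)) == expected

    def test_unknown_metabolism_level_is_error(self):
        with pytest.raises(ValueError):
            MetabolismAnnotation("x", "none")

    def test_codomains_under_exhaustive_level_enumeration(self):
        tox_values = set()
        pen_values = set()
        for combo in itertools.product(("high", "medium", "low"), repeat=4):
            tox_values.add(tox_points(risk(*combo)))
        for level in ("high", "medium", "low"):
            pen_values.add(metabolism_penalty(MetabolismAnnotation("x", level)))
        assert tox_values == set(range(0, 81, 10))
        assert pen_values == {-20, -15, -10}


class TestComposite:
    def test_single_target_sum(self):
        c = ScoreComponents(8.0, 50.0, 30, 60, -15)
        assert composite_score([c]) == pytest.approx(133.0)

    def test_all_zero_with_penalty(self):
        c = ScoreComponents(0.0, 0.0, 0, 0, -10)
        assert composite_score([c]) == pytest.approx(-10.0)

    def test_two_targets_ligand_terms_counted_once(self):
        a = ScoreComponents(10.93, 53.85, 10, 40, -15)
        b = ScoreComponents(8.0, 50.0, 10, 40, -15)
        assert composite_score([a, b]) == pytest.approx(157.78)

    def test_matches_independent_resummation(self):
        rng = random.Random(123)
        for _ in range(1000):
            n_targets = rng.randint(1, 3)
            comps = [
                ScoreComponents(
                    rng.randrange(0, 64) / 4.0,
                    rng.randrange(0, 401) / 4.0,
                    rng.choice((0, 10, 20, 30, 40)),
                    rng.choice(range(0, 81, 10)),
                    rng.choice((-20, -15, -10)),
                )
                for _ in range(n_targets)
            ]
            # independent oracle: sum ligand-level terms first, then energy+sim
            expected = (
                comps[0].lipinski_points
                + comps[0].tox_points
                + comps[0].metabolism_penalty
                + sum(c.abs_be for c in comps)
                + sum(c.sim_bm for c in comps)
            )
            assert composite_score(comps) == expected

    def test_empty_components_is_error(self):
        with pytest.raises(ValueError):
            composite_score([])


class TestRanking:
    def _rec(self, lid, score):
        return VSRecord(lid, {"T": ScoreComponents(0, 0, 0, 0, -10)}, composite=score)

    def test_descending_order(self):
        ranked = rank_library([self._rec("A", 10.0), self._rec("B", 20.0)])
        assert [r.ligand_id for r in ranked] == ["B", "A"]
        assert [r.rank for r in ranked] == [1, 2]

    def test_ties_broken_by_id(self):
        ranked = rank_library([self._rec("B", 10.0), self._rec("A", 10.0)])
        assert [r.ligand_id for r in ranked] == ["A", "B"]

    def test_empty_library(self):
        assert rank_library([]) == []

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_library([self._rec("A", 1.0), self._rec("A", 2.0)])

    def test_permutation_stable(self):
        rng = random.Random(5)
        records = [self._rec(f"L{i}", rng.choice((1.0, 2.0, 3.0))) for i in range(30)]
        ranked_a = [r.ligand_id for r in rank_library(list(records))]
        rng.shuffle(records)
        ranked_b = [r.ligand_id for r in rank_library(records)]
        assert ranked_a == ranked_b
        assert sorted(r.rank for r in rank_library(records)) == list(range(1, 31))
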
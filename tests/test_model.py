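"""Model representation, expression expansion, state codec, file round-trips."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sdds
from sdds import (
    ModelParseError,
    ModelValidationError,
    PropensityPair,
    StateSpace,
    parse_model,
    random_model,
    state_from_string,
    state_to_string,
    write_model,
)
from sdds.expr import ExpressionError, parse_rule_expression


class TestStateSpace:
    def test_total_states_is_product_of_cardinalities(self):
        space = StateSpace(("a", "b", "c"), (3, 4, 2))
        assert space.n == 3
        assert space.total_states == 24
        assert len(list(space.states())) == 24

    @pytest.mark.parametrize(
        "names,cards",
        [(("a",), (1,)), ((), ()), (("a", "a"), (2, 2)), (("a",), (2, 2))],
    )
    def test_invalid_spaces_rejected(self, names, cards):
        with pytest.raises(ModelValidationError):
            StateSpace(names, cards)

    def test_rank_roundtrip_is_lexicographic(self):
        space = StateSpace(("a", "b", "c"), (3, 4, 2))
        ranks = [space.index(s) for s in space.states()]
        assert ranks == list(range(24))  # variable 1 most significant
        for rank, s in enumerate(space.states()):
            assert space.state_at(rank) == s


class TestStateStrings:
    @pytest.mark.parametrize(
        "string,cards,levels",
        [
            ("0011", (3, 2, 2, 2), (0, 0, 1, 1)),  # p53 damage-introduced state
            ("2000", (3, 4, 2, 2), (2, 0, 0, 0)),  # lambda lysogenic state
            ("031", (2, 4, 2), (0, 3, 1)),
        ],
    )
    def test_positional_decoding(self, string, cards, levels):
        space = StateSpace(tuple(f"v{i}" for i in range(len(cards))), cards)
        assert state_from_string(string, space) == levels
        assert state_to_string(levels, space) == string

    @pytest.mark.parametrize("bad", ["001", "00111", "0021", "00a1"])
    def test_malformed_strings_rejected(self, bad):
        space = StateSpace(("P", "Mc", "Mn", "Dam"), (3, 2, 2, 2))
        with pytest.raises(ModelValidationError):
            state_from_string(bad, space)

    def test_large_cardinalities_need_tuple_notation(self):
        space = StateSpace(("a", "b"), (2, 12))
        with pytest.raises(ModelValidationError):
            state_from_string("03", space)

    @given(st.lists(st.integers(min_value=2, max_value=10), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_encode_decode_bijection(self, cards):
        space = StateSpace(tuple(f"v{i}" for i in range(len(cards))), tuple(cards))
        seen = set()
        for s in space.states():
            encoded = state_to_string(s, space)
            assert state_from_string(encoded, space) == s
            seen.add(encoded)
        assert len(seen) == space.total_states


class TestExpressions:
    def test_expression_agrees_with_manual_table(self):
        space = StateSpace(("x1", "x2"), (2, 2))
        rule = parse_rule_expression("min(x1, not(x2))", 1, space)
        for x in space.states():
            assert rule(x, space) == min(x[0], 1 - x[1])

    def test_complement_uses_variable_cardinality(self):
        space = StateSpace(("a", "b"), (4, 2))
        rule = parse_rule_expression("not(a)", 0, space)
        assert [rule((v, 0), space) for v in range(4)] == [3, 2, 1, 0]

    def test_thresholds_and_conditionals(self):
        space = StateSpace(("CI", "CRO"), (3, 4))
        rule = parse_rule_expression("2 if CRO == 0 else min(CI, CRO >= 2)", 0, space)
        for ci, cro in space.states():
            expected = 2 if cro == 0 else min(ci, int(cro >= 2))
            assert rule((ci, cro), space) == expected

    @pytest.mark.parametrize(
        "expr", ["x1 / x2", "foo(x1)", "x3", "min(x1)", "not(x1 + 1)", "x1 **"]
    )
    def test_grammar_violations_rejected(self, expr):
        space = StateSpace(("x1", "x2"), (2, 2))
        with pytest.raises(ExpressionError):
            parse_rule_expression(expr, 0, space)

    def test_out_of_codomain_expression_rejected(self):
        space = StateSpace(("x1", "x2"), (2, 2))
        with pytest.raises(ModelValidationError):
            parse_rule_expression("x1 + x2", 0, space)


MINIMAL = {
    "variables": [{"name": "x1", "levels": 2}, {"name": "x2", "levels": 2}],
    "rules": {"x1": "x2", "x2": "min(x1, not(x2))"},
    "propensities": {
        "x1": {"up": 0.1, "down": 0.2},
        "x2": {"up": 0.5, "down": 0.9},
    },
}


class TestParsing:
    def test_expression_model_matches_expected_truth_table(self, example):
        model = parse_model(json.dumps(MINIMAL))
        assert model.rules_equal(example)
        assert [(p.up, p.down) for p in model.propensities] == [(0.1, 0.2), (0.5, 0.9)]

    def test_identity_single_variable_model(self):
        doc = {
            "variables": [{"name": "x1", "levels": 2}],
            "rules": {"x1": "x1"},
            "propensities": {"x1": {"up": 0.5, "down": 0.5}},
        }
        model = parse_model(json.dumps(doc))
        for x in model.space.states():
            assert model.image(x) == x

    def test_propensity_outside_unit_interval_rejected(self):
        doc = json.loads(json.dumps(MINIMAL))
        doc["propensities"]["x1"]["up"] = 1.3
        with pytest.raises(ModelValidationError):
            parse_model(json.dumps(doc))

    def test_missing_propensity_rejected(self):
        doc = json.loads(json.dumps(MINIMAL))
        del doc["propensities"]["x2"]
        with pytest.raises(ModelValidationError):
            parse_model(json.dumps(doc))

    def test_rule_output_outside_levels_rejected(self):
        doc = json.loads(json.dumps(MINIMAL))
        doc["rules"]["x1"] = {"inputs": ["x2"], "table": [0, 2]}
        with pytest.raises(ModelValidationError):
            parse_model(json.dumps(doc))

    def test_malformed_syntax_names_location(self):
        with pytest.raises(ModelParseError, match="line"):
            parse_model('{"variables": [,]}')

    def test_named_table_reference(self):
        doc = json.loads(json.dumps(MINIMAL))
        doc["rules"]["x1"] = "@t1"
        doc["tables"] = {"t1": [0, 1, 0, 1]}  # x2 copied, full-space table
        model = parse_model(json.dumps(doc))
        assert model.rules_equal(parse_model(json.dumps(MINIMAL)))


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["json", "tsv"])
    @pytest.mark.parametrize("name", sdds.FIXTURE_NAMES)
    def test_fixture_round_trip(self, name, dialect):
        model = sdds.load_fixture(name)
        back = parse_model(write_model(model, dialect), dialect)
        assert model.rules_equal(back)
        assert model.propensities == back.propensities

    def test_random_model_round_trips(self):
        rng = np.random.default_rng(2024)
        for k in range(200):
            cards = tuple(rng.integers(2, 5, size=rng.integers(1, 5)))
            model = random_model(cardinalities=cards, seed=int(rng.integers(2**31)))
            for dialect in ("json", "tsv"):
                back = parse_model(write_model(model, dialect), dialect)
                assert model.rules_equal(back), (k, dialect)
                assert model.propensities == back.propensities

    def test_mixed_cardinality_round_trip(self, lam):
        # CRO has four levels; both dialects must carry multilevel tables
        back = parse_model(write_model(lam, "tsv"), "tsv")
        assert lam.rules_equal(back)


class TestWorkedExampleReconstruction:
    def test_rules_uniquely_determined_by_printed_probabilities(self, example):
        """Brute force: of all 256 Boolean rule pairs, exactly one admits
        propensities reproducing the eleven documented transition
        probabilities, and it is the bundled one."""
        from sdds.fixtures import EXAMPLE_TRANSITIONS

        space = example.space
        states = list(space.states())
        printed = {
            (tuple(int(c) for c in s), tuple(int(c) for c in t)): w
            for (s, t), w in EXAMPLE_TRANSITIONS.items()
        }
        consistent = []
        for f1 in itertools.product((0, 1), repeat=4):
            for f2 in itertools.product((0, 1), repeat=4):
                rules = {s: (f1[i], f2[i]) for i, s in enumerate(states)}
                sol = _solve_propensities(states, rules, printed)
                if sol is not None:
                    consistent.append((f1, f2, sol))
        assert len(consistent) == 1
        f1, f2, sol = consistent[0]
        assert {s: (f1[i], f2[i]) for i, s in enumerate(states)} == {
            s: example.image(s) for s in states
        }
        assert sol == {(0, "up"): 0.1, (0, "down"): 0.2, (1, "up"): 0.5, (1, "down"): 0.9}


def _solve_propensities(states, rules, printed):
    """Given candidate rules, solve for per-coordinate move probabilities
    from the printed transition table; None if inconsistent."""
    solution = {}
    for s in states:
        image = rules[s]
        marginals = []
        for i in range(2):
            if image[i] == s[i]:
                # coordinate frozen: any printed move of it contradicts
                if any(t[i] != s[i] and printed.get((s, t), 0) > 0 for t in states):
                    return None
                marginals.append(None)
            else:
                move = sum(printed.get((s, t), 0.0) for t in states if t[i] == image[i])
                direction = "up" if s[i] < image[i] else "down"
                key = (i, direction)
                if key in solution and abs(solution[key] - move) > 1e-12:
                    return None
                solution[key] = move
                marginals.append(move)
        # transition probabilities must factor as the product of marginals
        for t in states:
            w = 1.0
            for i in range(2):
                if t[i] == image[i] and image[i] != s[i]:
                    w *= marginals[i]
                elif t[i] == s[i]:
                    w *= 1.0 if marginals[i] is None else 1.0 - marginals[i]
                else:
                    w = 0.0
            if abs(w - printed.get((s, t), 0.0)) > 1e-12:
                return None
    return {k: round(v, 10) for k, v in solution.items()}
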
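"""Discrete-function representation, canalization, signs, dominant rules."""

import itertools

import pytest

from grnlogic.core import (
    DiscreteFunction,
    EdgeSign,
    detect_dominant,
    edge_sign,
    is_monotone,
    load_truth_table,
    dump_truth_table,
    nested_canalization,
    random_function,
)

from conftest import all_boolean_functions, random_tables


# ---------------------------------------------------------------------------
# Evaluation and indexing
# ---------------------------------------------------------------------------

class TestEvaluate:
    def test_fancm_expressed_only_without_icl(self, fancm):
        assert fancm([1, 0]) == 1
        assert fancm([1, 1]) == 0
        assert fancm([0, 0]) == 0

    def test_constant_rule(self):
        f = DiscreteFunction(3, 2, (0,) * 8)
        for x in f.inputs():
            assert f(x) == 0

    def test_first_variable_most_significant(self):
        # f(x1, x2) = x1 in base 3: index = 3*x1 + x2
        f = DiscreteFunction(2, 3, (0, 0, 0, 1, 1, 1, 2, 2, 2))
        assert f([2, 0]) == 2 and f([0, 2]) == 0

    @pytest.mark.parametrize("bad", [[0], [0, 0, 0], [0, 2]])
    def test_input_validation(self, fancm, bad):
        with pytest.raises(ValueError):
            fancm(bad)

    def test_table_length_validated(self):
        with pytest.raises(ValueError):
            DiscreteFunction(2, 2, (0, 1, 0))

    def test_restrict_drops_variable(self, fancm):
        g = fancm.restrict({2: 0})  # ICL silenced: copies CHKREC
        assert g.k == 1 and g.table == (0, 1)


class TestTruthTableText:
    def test_round_trip(self, add):
        assert load_truth_table(dump_truth_table(add)).table == add.table

    def test_bare_output_column(self):
        f = load_truth_table("2 2\n0\n0\n1\n0\n")
        assert f.table == (0, 0, 1, 0)

    def test_coordinate_order_enforced(self):
        with pytest.raises(ValueError):
            load_truth_table("1 2\n1 : 0\n0 : 1\n")


# ---------------------------------------------------------------------------
# Nested canalization
# ---------------------------------------------------------------------------

class TestNestedCanalization:
    def test_add_layer_order(self, add):
        """The 5-input ADD rule peels in the order x2, x5, x3, x1, x4 with
        FAN1=1 silencing the gene at the first layer."""
        nc = nested_canalization(add)
        assert [layer.variable for layer in nc] == [2, 5, 3, 1, 4]
        first = nc[0]
        assert first.canalizing_values == (1,)
        assert first.canalized_values == (0,)

    def test_xor_is_not_canalizing(self, xor2):
        assert len(nested_canalization(xor2)) == 0

    def test_and_first_layer(self):
        f = DiscreteFunction(2, 2, (0, 0, 0, 1))
        nc = nested_canalization(f)
        assert nc[0].variable == 1
        assert dict(nc[0].value_map) == {0: 0}

    def test_boolean_layers_are_singletons(self):
        for f in random_tables(50, 3, 2, seed=11):
            for layer in nested_canalization(f):
                assert len(layer.canalizing_values) == 1
                assert len(layer.canalized_values) == 1

    @pytest.mark.parametrize("k,m,seed", [(2, 2, 0), (3, 2, 1), (4, 2, 2),
                                          (2, 3, 3), (3, 3, 4), (4, 3, 5)])
    def test_round_trip_reconstruction(self, k, m, seed):
        """Replaying the layer case analysis over the residual table gives
        back the source rule exactly."""
        for f in random_tables(25, k, m, seed=seed):
            assert nested_canalization(f).reconstruct().table == f.table

    def test_layer_cardinality_invariant(self):
        for f in random_tables(40, 3, 3, seed=21):
            for layer in nested_canalization(f):
                s_in = layer.canalizing_values
                s_out = layer.canalized_values
                assert len(s_out) <= len(s_in) <= f.m - 1


# ---------------------------------------------------------------------------
# Edge signs and monotonicity
# ---------------------------------------------------------------------------

def _sign_oracle(f, i):
    """All-pairs comparison over every context, written independently."""
    up = down = False
    for x in f.inputs():
        for j in range(f.m):
            if j <= x[i - 1]:
                continue
            y = list(x)
            y[i - 1] = j
            if f(x) < f(y):
                up = True
            if f(x) > f(y):
                down = True
    if up and down:
        return "hybrid"
    if up:
        return "positive"
    if down:
        return "negative"
    return "null"


class TestEdgeSign:
    def test_fancm_signs(self, fancm):
        assert edge_sign(fancm, 1) is EdgeSign.POSITIVE  # CHKREC
        assert edge_sign(fancm, 2) is EdgeSign.NEGATIVE  # ICL

    def test_constant_is_null(self):
        f = DiscreteFunction(2, 2, (1, 1, 1, 1))
        assert edge_sign(f, 1) is EdgeSign.NULL

    def test_xor_is_hybrid(self, xor2):
        assert edge_sign(xor2, 1) is EdgeSign.HYBRID

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_oracle_on_all_boolean_functions(self, k):
        for f in all_boolean_functions(k):
            for i in range(1, k + 1):
                assert edge_sign(f, i).value == _sign_oracle(f, i)

    def test_multivalued_against_oracle(self):
        for f in random_tables(40, 3, 3, seed=31):
            for i in range(1, 4):
                assert edge_sign(f, i).value == _sign_oracle(f, i)

    def test_index_out_of_range(self, fancm):
        with pytest.raises(ValueError):
            edge_sign(fancm, 3)


class TestMonotone:
    def test_or_is_increasing(self):
        f = DiscreteFunction.from_callable(3, 2, lambda x: max(x))
        assert is_monotone(f, "increasing")
        assert not is_monotone(f, "decreasing")

    def test_fancm_is_not_increasing(self, fancm):
        assert not is_monotone(fancm, "increasing")

    def test_constant_is_vacuously_monotone(self):
        f = DiscreteFunction(2, 2, (1, 1, 1, 1))
        assert is_monotone(f, "increasing")
        assert is_monotone(f, "decreasing")


# ---------------------------------------------------------------------------
# Dominant rules
# ---------------------------------------------------------------------------

class TestDominant:
    def test_majority_has_witness(self):
        f = DiscreteFunction.from_callable(
            3, 2, lambda x: 1 if sum(x) >= 2 else 0)
        form = detect_dominant(f)
        assert form is not None
        for x in f.inputs():
            assert form(x) == f(x)

    def test_xor_has_no_state_count_witness(self, xor2):
        assert detect_dominant(xor2) is None

    def test_witness_reevaluates_when_returned(self):
        # dominant rules are vanishingly rare among random tables, so mix
        # generated members of the class into the scan
        pool = random_tables(20, 3, 3, seed=41) + \
            [random_function(3, 3, "dominant", seed=s) for s in range(5)]
        hits = 0
        for f in pool:
            form = detect_dominant(f)
            if form is not None:
                hits += 1
                for x in f.inputs():
                    assert form(x) == f(x)
        assert hits >= 5

    def test_generated_dominant_rules_are_detected(self):
        for seed in range(8):
            f = random_function(3, 3, "dominant", seed=seed)
            assert detect_dominant(f) is not None


# ---------------------------------------------------------------------------
# Random generation
# ---------------------------------------------------------------------------

class TestRandomFunction:
    def test_deterministic_under_seed(self):
        a = random_function(2, 2, "uniform", seed=99)
        b = random_function(2, 2, "uniform", seed=99)
        assert a.table == b.table

    @pytest.mark.parametrize("kind", ["uniform", "canalizing", "threshold",
                                      "dominant"])
    def test_all_kinds_produce_valid_tables(self, kind):
        f = random_function(3, 3, kind, seed=7)
        assert len(f.table) == 27 and all(0 <= v < 3 for v in f.table)

    def test_canalizing_generation_reaches_depth(self):
        for seed in range(10):
            f = random_function(3, 2, "canalizing", seed=seed, layers=1)
            assert nested_canalization(f).depth >= 1
        for seed in range(10):
            f = random_function(4, 3, "canalizing", seed=seed, layers=2,
                                canalizing_values=1)
            assert nested_canalization(f).depth >= 2

    def test_threshold_generation_is_order_one(self):
        from grnlogic.measures import threshold_form
        for seed in range(5):
            f = random_function(4, 3, "threshold", seed=seed)
            assert threshold_form(f, max_order=1) is not None

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            random_function(2, 2, "canalizing", seed=0, layers=3)
        with pytest.raises(ValueError):
            random_function(2, 2, "canalizing", seed=0, canalizing_values=2)
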
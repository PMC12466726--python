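from itertools import combinations, permutations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from wqbench import (
    CANONICAL_DIMENSIONS,
    DEFAULT_MEASURE,
    FuzzyMeasure,
    MeasureError,
    WQCategory,
    choquet_integral,
    classify_final,
    validate_measure,
)

TABLE5_PROFILE = {"WQ": 0.50, "Past": 0.75, "Best": 1.00, "Competitor": 0.50}


def all_subsets(dims):
    for r in range(len(dims) + 1):
        yield from (frozenset(c) for c in combinations(dims, r))


def mobius_choquet(profile, measure):
    """Independent oracle: Choquet via the Moebius transform,

    C(x) = sum over subsets A of m(A) * min_{i in A} x_i,
    m(A) = sum over B subseteq A of (-1)^{|A \\ B|} mu(B).
    """
    dims = tuple(profile)
    total = 0.0
    for a in all_subsets(dims):
        if not a:
            continue
        m = 0.0
        for r in range(len(a) + 1):
            for b in combinations(sorted(a), r):
                m += (-1) ** (len(a) - len(b)) * measure[frozenset(b)]
        total += m * min(profile[d] for d in a)
    return total


def random_measure(dims, values):
    """Build a (generally non-monotone) measure from a value list."""
    subsets = [s for s in all_subsets(dims) if s and len(s) < len(dims)]
    mu = {s: v for s, v in zip(subsets, values)}
    mu[frozenset(dims)] = 1.0
    return FuzzyMeasure(dims, mu)


class TestWorkedAggregation:
    def test_scaled_score_and_category(self):
        """The elicited measure aggregates the worked profile to 62.50."""
        result = choquet_integral(TABLE5_PROFILE, DEFAULT_MEASURE)
        assert result.scaled == pytest.approx(62.50)
        assert result.category is WQCategory.ENHANCED

    def test_trace_is_deterministic_chain(self):
        result = choquet_integral(TABLE5_PROFILE, DEFAULT_MEASURE)
        order = [s.dimension for s in result.trace]
        # ties (0.50, 0.50) break alphabetically for a stable trace
        assert order == ["Competitor", "WQ", "Past", "Best"]
        assert sum(s.increment * s.measure for s in result.trace) == pytest.approx(0.625)

    def test_missing_dimension(self):
        with pytest.raises(ValueError, match="missing"):
            choquet_integral({"WQ": 0.5}, DEFAULT_MEASURE)


class TestChoquetProperties:
    @given(st.tuples(*(st.floats(0, 1) for _ in range(4))))
    def test_idempotency(self, _values):
        v = _values[0]
        profile = {d: v for d in CANONICAL_DIMENSIONS}
        assert choquet_integral(profile, DEFAULT_MEASURE).choquet == pytest.approx(v)

    @given(
        st.tuples(*(st.floats(0, 1) for _ in range(4))),
        st.tuples(*(st.floats(0.01, 1) for _ in range(4))),
    )
    def test_additive_measure_is_weighted_sum(self, values, raw_weights):
        total = sum(raw_weights)
        weights = {d: w / total for d, w in zip(CANONICAL_DIMENSIONS, raw_weights)}
        measure = FuzzyMeasure.additive(weights)
        profile = dict(zip(CANONICAL_DIMENSIONS, values))
        expected = sum(weights[d] * profile[d] for d in CANONICAL_DIMENSIONS)
        assert choquet_integral(profile, measure).choquet == pytest.approx(expected)

    @given(
        st.integers(2, 5),
        st.lists(st.floats(0, 1), min_size=35, max_size=35),
        st.lists(st.floats(0, 1), min_size=5, max_size=5),
    )
    def test_matches_mobius_oracle(self, n, mu_values, x_values):
        """Sorted-chain evaluation equals the Moebius-transform expansion on
        random (monotone or not) measures for n <= 5."""
        dims = tuple(f"D{i}" for i in range(n))
        measure = random_measure(dims, mu_values)
        profile = dict(zip(dims, x_values))
        got = choquet_integral(profile, measure).choquet
        assert got == pytest.approx(mobius_choquet(profile, measure), abs=1e-9)

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_comonotonic_additivity(self, base):
        """C(x + y) = C(x) + C(y) for comonotone x, y (shared sort order)."""
        x = dict(zip(CANONICAL_DIMENSIONS, sorted(base)))
        y = {d: v / 2 for d, v in x.items()}  # same ordering as x
        both = {d: x[d] + y[d] for d in x}
        cx = choquet_integral(x, DEFAULT_MEASURE).choquet
        cy = choquet_integral(y, DEFAULT_MEASURE).choquet
        cxy = choquet_integral(both, DEFAULT_MEASURE).choquet
        assert cxy == pytest.approx(cx + cy, abs=1e-9)

    @given(
        st.tuples(*(st.floats(0, 1) for _ in range(4))),
        st.tuples(*(st.floats(0, 0.5) for _ in range(4))),
        st.lists(st.floats(0, 1), min_size=14, max_size=14),
    )
    def test_monotone_measure_gives_monotone_integral(self, values, bumps, seeds):
        """With a monotone capacity, raising any input never lowers C."""
        dims = CANONICAL_DIMENSIONS
        # construct a monotone measure: mu(A) = max over chains via sorting
        mu = {}
        subsets = [s for s in all_subsets(dims) if s and len(s) < len(dims)]
        for s, v in zip(subsets, seeds):
            mu[s] = v
        # enforce monotonicity by taking the running max over subset size
        for s in sorted(mu, key=len):
            parents = [t for t in mu if t < s]
            mu[s] = max([mu[s]] + [mu[t] for t in parents])
        mu = {s: min(v, 1.0) for s, v in mu.items()}
        mu[frozenset(dims)] = 1.0
        measure = FuzzyMeasure(dims, mu)
        assert not measure.validate().monotonicity_violations
        profile = dict(zip(dims, values))
        bumped = {
            d: min(v + b, 1.0) for (d, v), b in zip(profile.items(), bumps)
        }
        assert (
            choquet_integral(bumped, measure).choquet
            >= choquet_integral(profile, measure).choquet - 1e-9
        )

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=3))
    def test_permutation_invariance(self, values):
        """Relabelling dimensions in profile and measure together leaves C
        unchanged."""
        dims = ("A", "B", "C")
        mu_values = [0.3, 0.6, 0.1, 0.8, 0.2, 0.5]
        base_measure = random_measure(dims, mu_values)
        base_profile = dict(zip(dims, values))
        base = choquet_integral(base_profile, base_measure).choquet
        for perm in permutations(dims):
            relabel = dict(zip(dims, perm))
            mu = {
                frozenset(relabel[d] for d in s): base_measure[s]
                for s in all_subsets(dims)
            }
            measure = FuzzyMeasure(dims, mu)
            profile = {relabel[d]: v for d, v in base_profile.items()}
            assert choquet_integral(profile, measure).choquet == pytest.approx(base)

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_degenerate_measures_give_min_and_max(self, values):
        dims = CANONICAL_DIMENSIONS
        profile = dict(zip(dims, values))
        max_mu = {s: 1.0 for s in all_subsets(dims) if s}
        min_mu = {s: 0.0 for s in all_subsets(dims) if s and len(s) < len(dims)}
        min_mu[frozenset(dims)] = 1.0
        assert choquet_integral(profile, FuzzyMeasure(dims, max_mu)).choquet == pytest.approx(max(values))
        assert choquet_integral(profile, FuzzyMeasure(dims, min_mu)).choquet == pytest.approx(min(values))


class TestMeasureValidation:
    def test_default_measure_reports_known_violation(self):
        report = validate_measure(DEFAULT_MEASURE)
        assert report.ok
        pairs = {
            (frozenset(a), frozenset(b))
            for a, b, _, _ in report.monotonicity_violations
        }
        assert (frozenset({"WQ"}), frozenset({"Past", "WQ"})) in pairs

    def test_additive_measure_clean(self):
        measure = FuzzyMeasure.additive({d: 0.25 for d in CANONICAL_DIMENSIONS})
        report = validate_measure(measure)
        assert report.ok and not report.monotonicity_violations

    def test_nonzero_empty_set_rejected(self):
        with pytest.raises(MeasureError, match="empty"):
            FuzzyMeasure(("A", "B"), {frozenset(): 0.1, frozenset({"A", "B"}): 1.0})

    def test_out_of_range_value_rejected(self):
        with pytest.raises(MeasureError, match="outside"):
            FuzzyMeasure(("A", "B"), {frozenset({"A"}): 1.2})

    def test_json_round_trip(self):
        again = FuzzyMeasure.from_json(DEFAULT_MEASURE.to_json())
        for s in DEFAULT_MEASURE.subsets():
            assert again[s] == DEFAULT_MEASURE[s]
            assert again.provenance[s] == DEFAULT_MEASURE.provenance[s]

    def test_full_set_defaults_to_one(self):
        assert DEFAULT_MEASURE[CANONICAL_DIMENSIONS] == 1.0
        assert DEFAULT_MEASURE.provenance[frozenset(CANONICAL_DIMENSIONS)] == "defaulted"


class TestClassifyFinal:
    @pytest.mark.parametrize(
        "scaled,expected",
        [
            (62.5, WQCategory.ENHANCED),
            (100.0, WQCategory.EXCELLENT),
            (25.0, WQCategory.NOT_CLASSIFIED),
            (0.0, WQCategory.NOT_CLASSIFIED),
            (25.01, WQCategory.ACCEPTABLE),
            (50.0, WQCategory.ACCEPTABLE),
            (75.0, WQCategory.ENHANCED),
            (75.01, WQCategory.EXCELLENT),
        ],
    )
    def test_bands(self, scaled, expected):
        assert classify_final(scaled) is expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_final(101.0)
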
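import pytest
from hypothesis import given
from hypothesis import strategies as st

from wqbench import (
    CANONICAL_DIMENSIONS,
    DEFAULT_IMPORTANCE_SCALE,
    ExpertImportanceResponse,
    ExpertPanel,
    ExpertThresholdResponse,
    MissingSubsetError,
    TriangularMF,
    average_triangles,
    build_fuzzy_measure,
    build_threshold_category,
    centroid_defuzzify,
)

triangle_st = st.tuples(st.floats(0, 50), st.floats(0, 50), st.floats(0, 50)).map(
    lambda t: TriangularMF(*sorted(t))
)


def numeric_centroid(mf: TriangularMF, n=20_001):
    """Oracle: centre of gravity by numeric integration of x*mu(x)."""
    lo, hi = mf.a - 1.0, mf.c + 1.0
    xs = [lo + (hi - lo) * i / (n - 1) for i in range(n)]
    num = sum(x * mf(x) for x in xs)
    den = sum(mf(x) for x in xs)
    return num / den


class TestTriangleConsensus:
    def test_worked_panel_average(self):
        """Two 'not at all', four 'slightly', two 'moderately' average to the
        slightly-important triangle, centroid 0.15."""
        tris = (
            [DEFAULT_IMPORTANCE_SCALE["not_at_all_important"]] * 2
            + [DEFAULT_IMPORTANCE_SCALE["slightly_important"]] * 4
            + [DEFAULT_IMPORTANCE_SCALE["moderately_important"]] * 2
        )
        avg = average_triangles(tris)
        assert (avg.a, avg.b, avg.c) == pytest.approx((0.10, 0.15, 0.20))
        assert centroid_defuzzify(avg) == pytest.approx(0.15)

    def test_single_triangle_identity(self):
        t = TriangularMF(0.2, 0.3, 0.4)
        assert average_triangles([t]) == t

    def test_midpoint(self):
        avg = average_triangles([TriangularMF(0, 0, 0), TriangularMF(1, 1, 1)])
        assert (avg.a, avg.b, avg.c) == (0.5, 0.5, 0.5)

    def test_empty_list(self):
        with pytest.raises(ValueError):
            average_triangles([])

    @given(st.lists(triangle_st, min_size=1, max_size=8))
    def test_centroid_commutes_with_averaging(self, triangles):
        """Both maps are affine, so averaging then defuzzifying equals
        defuzzifying then averaging."""
        lhs = centroid_defuzzify(average_triangles(triangles))
        rhs = sum(centroid_defuzzify(t) for t in triangles) / len(triangles)
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestCentroid:
    @pytest.mark.parametrize(
        "params,expected",
        [((0.10, 0.15, 0.20), 0.15), ((0, 0, 3), 1.0), ((2, 5, 8), 5.0)],
    )
    def test_closed_form(self, params, expected):
        assert centroid_defuzzify(TriangularMF(*params)) == pytest.approx(expected)

    @pytest.mark.parametrize("params", [(0, 0, 3), (1, 2, 6), (0.1, 0.15, 0.2)])
    def test_matches_numeric_integration(self, params):
        mf = TriangularMF(*params)
        assert centroid_defuzzify(mf) == pytest.approx(numeric_centroid(mf), abs=1e-3)


class TestThresholdCategories:
    def test_single_response_matches_preset_acceptable(self):
        tri = build_threshold_category(
            [ExpertThresholdResponse("E1", "acceptable", 95, 110)]
        )
        assert (tri.a, tri.b, tri.c) == (95.0, 102.5, 110.0)

    def test_mean_then_midpoint(self):
        tri = build_threshold_category(
            [
                ExpertThresholdResponse("E1", "x", 80, 100),
                ExpertThresholdResponse("E2", "x", 90, 120),
            ]
        )
        assert (tri.a, tri.b, tri.c) == (85.0, 97.5, 110.0)

    def test_zero_width_consensus_warns(self):
        with pytest.warns(UserWarning, match="zero-width"):
            tri = build_threshold_category(
                [ExpertThresholdResponse("E1", "x", 100, 100)]
            )
        assert (tri.a, tri.b, tri.c) == (100.0, 100.0, 100.0)

    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)),
            min_size=1,
            max_size=8,
        )
    )
    def test_peak_is_exact_midpoint(self, pairs):
        responses = [
            ExpertThresholdResponse(f"E{i}", "x", min(a, c), max(a, c))
            for i, (a, c) in enumerate(pairs)
        ]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tri = build_threshold_category(responses)
        assert tri.a <= tri.b <= tri.c
        assert tri.b == pytest.approx((tri.a + tri.c) / 2)

    @pytest.mark.parametrize(
        "a,b,c",
        [(95, 102.5, 110), (-50, -30, -10), (-30, -10, 10), (-10, 10, 30)],
    )
    def test_preset_strict_triangles_obey_midpoint_rule(self, a, b, c):
        """Where the shipped systems use symmetric triangles, the peak is the
        midpoint of the feet, consistent with the elicitation rule."""
        assert b == pytest.approx((a + c) / 2)


class TestBuildFuzzyMeasure:
    def _panel(self, label_by_subset):
        responses = [
            ExpertImportanceResponse("E1", frozenset(subset), label)
            for subset, label in label_by_subset.items()
        ]
        return ExpertPanel(experts=["E1"], importance_responses=responses)

    def _full_panel(self, label="important"):
        from itertools import combinations

        labels = {}
        for r in range(1, 4):
            for combo in combinations(CANONICAL_DIMENSIONS, r):
                labels[combo] = label
        return self._panel(labels)

    def test_identical_answers_recover_label_centroid(self):
        """Round trip: a unanimous panel recovers the label's centroid for
        every subset."""
        measure = build_fuzzy_measure(
            self._full_panel("extremely_important"), CANONICAL_DIMENSIONS
        )
        expected = centroid_defuzzify(DEFAULT_IMPORTANCE_SCALE["extremely_important"])
        assert expected == pytest.approx(0.45)
        for s in measure.subsets():
            if 0 < len(s) < 4:
                assert measure[s] == pytest.approx(expected)

    def test_boundaries_defaulted_with_provenance(self):
        measure = build_fuzzy_measure(self._full_panel(), CANONICAL_DIMENSIONS)
        assert measure[frozenset()] == 0.0
        assert measure[frozenset(CANONICAL_DIMENSIONS)] == 1.0
        assert measure.provenance[frozenset()] == "defaulted"
        assert measure.provenance[frozenset({"WQ"})] == "elicited"

    def test_mixed_panel_subset_value(self):
        """The eight-expert 2/4/2 split gives 0.15 for its subset."""
        subset = frozenset({"Past", "Competitor"})
        labels = (
            ["not_at_all_important"] * 2
            + ["slightly_important"] * 4
            + ["moderately_important"] * 2
        )
        responses = [
            ExpertImportanceResponse(f"E{i + 1}", subset, lab)
            for i, lab in enumerate(labels)
        ]
        # fill the remaining subsets so the measure is complete
        from itertools import combinations

        for r in range(1, 4):
            for combo in combinations(CANONICAL_DIMENSIONS, r):
                if frozenset(combo) != subset:
                    responses.append(
                        ExpertImportanceResponse("E1", frozenset(combo), "important")
                    )
        panel = ExpertPanel(
            experts=[f"E{i + 1}" for i in range(8)], importance_responses=responses
        )
        measure = build_fuzzy_measure(panel, CANONICAL_DIMENSIONS)
        assert measure[subset] == pytest.approx(0.15)

    def test_missing_subset_named(self):
        panel = self._panel({("WQ",): "important"})
        with pytest.raises(MissingSubsetError, match="Past"):
            build_fuzzy_measure(panel, CANONICAL_DIMENSIONS)

    def test_unknown_label_rejected(self):
        panel = self._full_panel("sort_of_important")
        with pytest.raises(ValueError, match="scale"):
            build_fuzzy_measure(panel, CANONICAL_DIMENSIONS)
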
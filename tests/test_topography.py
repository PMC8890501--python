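"""Epistasis classification, square enumeration, ruggedness and r/s."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ribolandscape import LibrarySpec, build_library
from ribolandscape.genotypes import RNA_ALPHABET, genotype_to_index
from ribolandscape.topography import (
    EPISTASIS_CLASSES,
    classify_square,
    classify_squares,
    enumerate_squares,
    roughness_slope,
    ruggedness,
    ruggedness_trend,
    square_corner_indices,
)

fitness_values = st.floats(
    min_value=0.0, max_value=10.0, allow_nan=False, allow_infinity=False
)


def sign_pattern_oracle(w0, wa, wb, wab, eps=0.0):
    """Independent classification from the sign of each mutation's effect.

    Effect signs within eps of zero count as agreeing; both preserved ->
    magnitude, one flipped -> sign, both flipped -> reciprocal sign.
    """
    w0, wa, wb, wab = (np.asarray(x, float) for x in (w0, wa, wb, wab))
    interaction = wab + w0 - wa - wb

    def flips(d_ref, d_alt):
        # strict sign reversal: product negative beyond tolerance
        return d_ref * d_alt < -eps * (np.abs(d_ref) + np.abs(d_alt) + eps)

    a_flip = flips(wa - w0, wab - wb)
    b_flip = flips(wb - w0, wab - wa)
    out = np.where(
        np.abs(interaction) <= eps,
        0,
        np.where(
            a_flip & b_flip, 3, np.where(a_flip | b_flip, 2, 1)
        ),
    )
    return out


def brute_force_squares(spec):
    """All 4-genotype squares by checking every 4-subset of the library."""
    library = build_library(spec)
    squares = set()
    for quad in itertools.combinations(library, 4):
        varying = [
            p for p in range(spec.n_positions)
            if len({g[p] for g in quad}) > 1
        ]
        if len(varying) != 2:
            continue
        i, j = varying
        a_alleles = sorted({g[i] for g in quad})
        b_alleles = sorted({g[j] for g in quad})
        if len(a_alleles) != 2 or len(b_alleles) != 2:
            continue
        combos = {(g[i], g[j]) for g in quad}
        if combos == set(itertools.product(a_alleles, b_alleles)):
            squares.add(frozenset(quad))
    return squares


class TestClassifySquare:
    @pytest.mark.parametrize(
        "square, expected",
        [
            ((1.0, 0.5, 0.5, 0.0), "none"),  # exactly additive
            ((1.0, 0.8, 0.8, 0.3), "magnitude"),  # both deleterious everywhere
            ((1.0, 0.2, 0.2, 1.5), "reciprocal_sign"),  # both effects flip
            ((1.0, 1.2, 0.5, 0.4), "sign"),  # only mutation A flips
        ],
    )
    def test_canonical_examples(self, square, expected):
        assert classify_square(*square) == expected

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            classify_square(1.0, np.nan, 0.5, 0.2)

    def test_agrees_with_sign_pattern_oracle(self, rng):
        n = 20_000
        w = rng.uniform(0.0, 3.0, size=(n, 4))
        codes = classify_squares(w[:, 0], w[:, 1], w[:, 2], w[:, 3])
        oracle = sign_pattern_oracle(w[:, 0], w[:, 1], w[:, 2], w[:, 3])
        assert (codes == oracle).all()

    def test_rotation_invariance(self, rng):
        """The class does not depend on which corner anchors the square."""
        n = 5000
        w = rng.uniform(0.0, 3.0, size=(n, 4))
        w0, wa, wb, wab = w.T
        framings = [
            (w0, wa, wb, wab),
            (w0, wb, wa, wab),  # swap which mutation is "A"
            (wa, w0, wab, wb),  # anchor at the A corner
            (wa, wab, w0, wb),
            (wb, wab, w0, wa),  # anchor at the B corner
            (wb, w0, wab, wa),
            (wab, wb, wa, w0),  # anchor at the double mutant
            (wab, wa, wb, w0),
        ]
        reference = classify_squares(*framings[0])
        for framing in framings[1:]:
            assert (classify_squares(*framing) == reference).all()

    def test_zero_effect_counts_as_sign_agreeing(self):
        # |WA - W0| = 0 must not register as a sign flip
        assert classify_square(1.0, 1.0, 0.5, 0.4, eps=1e-9) == "magnitude"


class TestEnumerateSquares:
    def test_single_position_has_no_squares(self, toy_spec1):
        assert list(enumerate_squares(toy_spec1)) == []

    def test_two_positions_yield_36_matching_brute_force(self, toy_spec2):
        anchored = list(enumerate_squares(toy_spec2))
        assert len(anchored) == 36
        as_corner_sets = set()
        for ref, i, j, a, b in anchored:
            wa = ref[:i] + a + ref[i + 1 :]
            wb = ref[:j] + b + ref[j + 1 :]
            wab = wa[:j] + b + wa[j + 1 :]
            as_corner_sets.add(frozenset({ref, wa, wb, wab}))
        assert len(as_corner_sets) == 36
        assert as_corner_sets == brute_force_squares(toy_spec2)

    def test_corner_index_table_matches_enumeration(self, toy_spec2):
        corners = square_corner_indices(2)
        assert corners.shape == (36, 4)
        table_sets = {frozenset(int(c) for c in row) for row in corners}
        enum_sets = set()
        for ref, i, j, a, b in enumerate_squares(toy_spec2):
            wa = ref[:i] + a + ref[i + 1 :]
            wb = ref[:j] + b + ref[j + 1 :]
            wab = wa[:j] + b + wa[j + 1 :]
            enum_sets.add(
                frozenset(genotype_to_index(g) for g in (ref, wa, wb, wab))
            )
        assert table_sets == enum_sets


class TestRuggedness:
    def _additive_fitness(self, spec, rng=None):
        effects = {
            (p, allele): 0.1 * (p + 1) * (1 + RNA_ALPHABET.index(allele))
            for p in range(spec.n_positions)
            for allele in RNA_ALPHABET
        }
        library = build_library(spec)
        values = [
            2.0 + sum(effects[(p, g[p])] for p in range(spec.n_positions))
            for g in library
        ]
        return pd.Series(values, index=library)

    def test_additive_landscape_has_zero_ruggedness(self, toy_spec2):
        fitness = self._additive_fitness(toy_spec2)
        res = ruggedness(fitness, toy_spec2, eps=1e-9)
        assert res.ruggedness == 0.0
        assert res.f_none == 1.0
        assert res.n_squares == 36

    def test_multiplicative_landscape_has_zero_sign_fraction(self, toy_spec2):
        additive = self._additive_fitness(toy_spec2)
        fitness = np.exp(additive - 2.0)
        res = ruggedness(fitness, toy_spec2, eps=1e-9)
        # monotone effects: magnitude epistasis only, no sign classes
        assert res.f_sign == 0.0 and res.f_reciprocal_sign == 0.0
        assert res.ruggedness == 0.0

    def test_fractions_and_formula_on_random_landscape(self, toy_spec2, rng):
        fitness = pd.Series(
            rng.uniform(0, 2, toy_spec2.library_size),
            index=build_library(toy_spec2),
        )
        res = ruggedness(fitness, toy_spec2)
        total = res.f_none + res.f_magnitude + res.f_sign + res.f_reciprocal_sign
        assert total == pytest.approx(1.0)
        assert res.ruggedness == pytest.approx(
            2 * res.f_reciprocal_sign + res.f_sign
        )
        assert 0.0 <= res.ruggedness <= 2.0

    def test_matches_hand_classification_on_toy(self, toy_spec2, rng):
        fitness = pd.Series(
            rng.uniform(0, 2, toy_spec2.library_size),
            index=build_library(toy_spec2),
        )
        counts = {name: 0 for name in EPISTASIS_CLASSES}
        for ref, i, j, a, b in enumerate_squares(toy_spec2):
            wa = ref[:i] + a + ref[i + 1 :]
            wb = ref[:j] + b + ref[j + 1 :]
            wab = wa[:j] + b + wa[j + 1 :]
            counts[
                classify_square(
                    fitness[ref], fitness[wa], fitness[wb], fitness[wab]
                )
            ] += 1
        res = ruggedness(fitness, toy_spec2)
        assert res.f_sign == pytest.approx(counts["sign"] / 36)
        assert res.f_reciprocal_sign == pytest.approx(
            counts["reciprocal_sign"] / 36
        )

    def test_missing_corner_squares_are_skipped(self, toy_spec2, rng):
        fitness = pd.Series(
            rng.uniform(0.1, 2, toy_spec2.library_size),
            index=build_library(toy_spec2),
        )
        fitness.iloc[3] = np.nan
        res = ruggedness(fitness, toy_spec2)
        # each genotype is a corner of exactly 9 squares in a 2-position library
        assert res.n_skipped == 9
        assert res.n_squares == 27


class TestClassifiedSquaresTable:
    def test_table_matches_ruggedness_fractions(self, toy_spec2, rng):
        from ribolandscape.topography import classified_squares_table

        fitness = pd.Series(
            rng.uniform(0, 2, toy_spec2.library_size),
            index=build_library(toy_spec2),
        )
        fitness.iloc[0] = np.nan
        table = classified_squares_table(fitness, toy_spec2)
        res = ruggedness(fitness, toy_spec2)
        assert len(table) == 36
        assert (table["class"] == "skipped").sum() == res.n_skipped
        classified = table[table["class"] != "skipped"]
        assert (classified["class"] == "sign").mean() == pytest.approx(
            res.f_sign
        )


class TestRoughnessSlope:
    def test_additive_landscape_fits_exactly(self, toy_spec2):
        fitness = TestRuggedness()._additive_fitness(toy_spec2)
        rs = roughness_slope(fitness, toy_spec2)
        assert rs.roughness < 1e-9
        assert rs.ratio < 1e-9
        assert rs.slope > 0

    def test_single_perturbation_creates_roughness(self, toy_spec2):
        fitness = TestRuggedness()._additive_fitness(toy_spec2)
        fitness.iloc[5] += 0.5
        rs = roughness_slope(fitness, toy_spec2)
        assert rs.roughness > 1e-3

    def test_matches_statsmodels_ols(self, toy_spec2, rng):
        import statsmodels.api as sm

        fitness = pd.Series(
            rng.uniform(0, 2, toy_spec2.library_size),
            index=build_library(toy_spec2),
        )
        rs = roughness_slope(fitness, toy_spec2)
        library = build_library(toy_spec2)
        wt = toy_spec2.wild_type_alleles
        X = pd.DataFrame(
            {
                f"pos{p}:{allele}": [float(g[p] == allele) for g in library]
                for p in range(2)
                for allele in RNA_ALPHABET
                if allele != wt[p]
            },
            index=library,
        )
        model = sm.OLS(fitness, sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            rs.coefficients.to_numpy(), model.params.iloc[1:].to_numpy(),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            rs.roughness,
            np.sqrt(np.mean(model.resid**2)),
            atol=1e-10,
        )


class TestRuggednessTrend:
    def test_perfect_monotone_trends(self):
        mg = [1, 2, 3, 4, 6, 8, 16, 48]
        decreasing = np.linspace(1.0, 0.1, 8)
        assert ruggedness_trend(mg, decreasing).rho == pytest.approx(-1.0)
        assert ruggedness_trend(mg, decreasing[::-1]).rho == pytest.approx(1.0)

    def test_constant_input_flagged_undefined(self):
        res = ruggedness_trend([1, 2, 3, 4], [0.5, 0.5, 0.5, 0.5])
        assert np.isnan(res.rho)

    def test_tied_triplicates_match_hand_ranked_spearman(self):
        mg = np.repeat([1.0, 2.0, 4.0, 8.0], 3)
        rug = np.repeat([0.8, 0.6, 0.4, 0.2], 3)

        def average_ranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x), float)
            sx = np.asarray(x)[order]
            i = 0
            while i < len(x):
                j = i
                while j < len(x) and sx[j] == sx[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        expected = np.corrcoef(average_ranks(mg), average_ranks(rug))[0, 1]
        res = ruggedness_trend(mg, rug)
        assert res.rho == pytest.approx(expected)
        assert res.rho < 0 and res.rho > -1.0 + 1e-12 or res.rho == -1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ruggedness_trend([1, 2], [0.1, 0.2])
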
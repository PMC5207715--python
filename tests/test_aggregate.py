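"""Hierarchical aggregation: group means, weighted combination, index
conversion and the two assembly paths."""

import math

import numpy as np
import pytest

from lpindex import (
    Dataset,
    GroupTrend,
    SpeciesTrend,
    ValidationWarning,
    WeightScheme,
    annualized_rate,
    assemble_lpi_d,
    assemble_lpi_u,
    exclude_low_representation,
    group_mean,
    lambdas_to_index,
    weighted_combine,
)

from conftest import exponential_series, make_record


def trend(years_to_lambda, window=(1970, 1980), binomial="sp"):
    yrs = np.arange(window[0], window[1] + 1)
    arr = np.full(yrs.shape, np.nan)
    for y, v in years_to_lambda.items():
        arr[y - window[0]] = v
    return SpeciesTrend(binomial, yrs, arr, np.isfinite(arr).astype(int))


class TestGroupMean:
    def test_mean_of_two_species(self):
        out = group_mean([trend({1971: 0.2}), trend({1971: -0.2})])
        assert out.lambdas[1] == pytest.approx(0.0)
        assert out.n_species[1] == 2

    def test_single_species_identity(self):
        out = group_mean([trend({1971: 0.3, 1975: -0.1})])
        assert out.lambdas[1] == 0.3 and out.lambdas[5] == -0.1

    def test_staggered_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        species = []
        values = []
        for i in range(5):
            start = 1971 + i
            vals = {y: rng.normal() for y in range(start, 1979)}
            values.append(vals)
            species.append(trend(vals))
        out = group_mean(species)
        for y in range(1970, 1981):
            contribs = [v[y] for v in values if y in v]
            idx = y - 1970
            if contribs:
                assert out.lambdas[idx] == pytest.approx(np.mean(contribs))
            else:
                assert np.isnan(out.lambdas[idx])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            group_mean([])


class TestWeightedCombine:
    def _child(self, years_to_lambda, window=(1970, 1980)):
        t = trend(years_to_lambda, window)
        return GroupTrend((), t.years, t.lambdas, t.n_populations)

    def test_proportional_weights(self):
        a = self._child({1971: -0.1})
        b = self._child({1971: 0.1})
        out = weighted_combine([a, b], [0.433, 0.567])
        assert out.lambdas[1] == pytest.approx(0.433 * -0.1 + 0.567 * 0.1)
        assert out.lambdas[1] == pytest.approx(0.0134)

    def test_equal_weights_symmetry(self):
        a = self._child({1971: 0.1})
        b = self._child({1971: -0.1})
        out = weighted_combine([a, b], [0.5, 0.5])
        assert out.lambdas[1] == pytest.approx(0.0)

    def test_absent_child_renormalizes(self):
        a = self._child({1971: 0.2, 1972: 0.3})
        b = self._child({1971: -0.2})  # absent in 1972
        out = weighted_combine([a, b], [0.25, 0.75])
        assert out.lambdas[1] == pytest.approx(0.25 * 0.2 + 0.75 * -0.2)
        assert out.lambdas[2] == pytest.approx(0.3)

    def test_zero_weight_on_all_present_children_raises(self):
        a = self._child({1971: 0.2})
        b = self._child({1972: 0.1})
        with pytest.raises(ValueError):
            weighted_combine([a, b], [0.0, 1.0])

    def test_negative_weight_raises(self):
        a = self._child({1971: 0.2})
        with pytest.raises(ValueError):
            weighted_combine([a], [-1.0])


class TestLambdasToIndex:
    def test_two_step_closed_form(self):
        out = lambdas_to_index({1971: 0.1, 1972: -0.1}, 1970)
        assert out == pytest.approx([1.0, 10**0.1, 1.0])

    def test_zero_rates_hold_at_one(self):
        out = lambdas_to_index({y: 0.0 for y in range(1971, 1981)}, 1970)
        assert np.allclose(out, 1.0)

    def test_constant_decline_closed_form(self):
        lam = {y: math.log10(0.98) for y in range(1971, 2013)}
        out = lambdas_to_index(lam, 1970)
        assert out[-1] == pytest.approx(0.98**42, rel=1e-12)

    def test_gap_raises_by_default(self):
        arr = np.array([np.nan, 0.1, np.nan, 0.1])
        with pytest.raises(ValueError):
            lambdas_to_index(arr, 1970)

    def test_gap_held_on_request(self):
        arr = np.array([np.nan, 0.1, np.nan, -0.1])
        out = lambdas_to_index(arr, 1970, on_missing="hold")
        assert out == pytest.approx([1.0, 10**0.1, 10**0.1, 1.0])


class TestAnnualizedRate:
    @pytest.mark.parametrize(
        "final_index, n_years, expected",
        [
            (0.42, 42, 2.04),
            (0.185, 42, 3.94),
            (1.0, 10, 0.0),
            (4.0, 2, -100.0),  # doubling each year
        ],
    )
    def test_values(self, final_index, n_years, expected):
        assert annualized_rate(final_index, n_years) == pytest.approx(
            expected, abs=0.005
        )

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            annualized_rate(0.0, 10)
        with pytest.raises(ValueError):
            annualized_rate(1.0, 0)


class TestAssembleU:
    def test_homogeneous_dataset_closed_form(self, window):
        # every subset shares the same constant rate
        records = []
        i = 0
        for zone in ("tropical", "temperate"):
            for system in ("terrestrial", "freshwater", "marine"):
                i += 1
                records.append(
                    make_record(f"p{i}", f"Sp {i}",
                                exponential_series(0.98, window),
                                system=system, zone=zone)
                )
        ds = Dataset(records, window)
        out = assemble_lpi_u(ds)
        n = window[1] - window[0]
        assert out.final() == pytest.approx(0.98**n, rel=1e-8)
        assert out.index[0] == 1.0

    def test_single_zone_equals_its_own_index(self, window):
        ds = Dataset(
            [make_record("p1", "Sp a", exponential_series(1.03, window),
                         zone="tropical")],
            window,
        )
        out = assemble_lpi_u(ds)
        n = window[1] - window[0]
        assert out.final() == pytest.approx(1.03**n, rel=1e-8)

    def test_two_zone_closed_form(self, window):
        a, b = math.log10(1.02), math.log10(0.97)
        ds = Dataset(
            [
                make_record("p1", "Sp a", exponential_series(1.02, window),
                            zone="tropical"),
                make_record("p2", "Sp b", exponential_series(0.97, window),
                            zone="temperate"),
            ],
            window,
        )
        out = assemble_lpi_u(ds)
        n = window[1] - window[0]
        assert out.final() == pytest.approx(10 ** (n * (a + b) / 2), rel=1e-8)

    def test_alternative_ordering_same_on_full_coverage(self, small_dataset):
        default = assemble_lpi_u(small_dataset)
        alt = assemble_lpi_u(small_dataset, order="zones_within_system")
        assert np.allclose(default.index, alt.index)


class TestAssembleD:
    def test_homogeneity_makes_weights_irrelevant(self, window):
        lam = math.log10(0.99)
        records = [
            make_record("p1", "Sp a", exponential_series(0.99, window)),
            make_record("p2", "Sp b", exponential_series(0.99, window),
                        group="Fish", system="freshwater"),
        ]
        ds = Dataset(records, window)
        w = WeightScheme(
            {
                ("terrestrial", "Palearctic", "Birds"): 0.9,
                ("freshwater", "Palearctic", "Fish"): 0.1,
            }
        )
        u = assemble_lpi_u(ds)
        d = assemble_lpi_d(ds, w)
        assert np.allclose(u.index, d.index, rtol=1e-10)
        n = window[1] - window[0]
        assert d.final() == pytest.approx(10 ** (n * lam), rel=1e-8)

    def test_two_group_weighted_closed_form(self, window):
        # one realm, two taxa with weights 0.9/0.1 and rates 10^(-0.01)/10^(0.01)
        records = [
            make_record("p1", "Sp a", exponential_series(10 ** -0.01, window)),
            make_record("p2", "Sp b", exponential_series(10 ** 0.01, window),
                        group="Fish"),
        ]
        ds = Dataset(records, window)
        w = WeightScheme(
            {
                ("terrestrial", "Palearctic", "Birds"): 0.9,
                ("terrestrial", "Palearctic", "Fish"): 0.1,
            }
        )
        out = assemble_lpi_d(ds, w)
        n = window[1] - window[0]
        expected = 10 ** (n * (0.9 * -0.01 + 0.1 * 0.01))
        assert out.final() == pytest.approx(expected, rel=1e-10)

    def test_unweighted_group_raises_with_keys(self, small_dataset):
        w = WeightScheme({("terrestrial", "Palearctic", "Birds"): 1.0})
        with pytest.raises(KeyError, match="freshwater"):
            assemble_lpi_d(small_dataset, w)

    def test_baseline_is_exactly_one(self, small_dataset, equal_weights):
        out = assemble_lpi_d(small_dataset, equal_weights)
        assert out.index[0] == 1.0

    def test_permutation_invariance(self, small_dataset, equal_weights):
        rev = Dataset(list(reversed(small_dataset.records)), small_dataset.window)
        a = assemble_lpi_d(small_dataset, equal_weights)
        b = assemble_lpi_d(rev, equal_weights)
        assert np.allclose(a.index, b.index, rtol=1e-12)


class TestExcludeLowRepresentation:
    def test_removes_groups_below_threshold(self, small_dataset):
        rep = {
            ("terrestrial", "Palearctic", "Birds"): 0.5,
            ("freshwater", "Palearctic", "Fish"): 0.007,
        }
        filtered, removed = exclude_low_representation(small_dataset, rep)
        assert removed == [("freshwater", "Palearctic", "Fish")]
        assert all(r.group == "Birds" for r in filtered.records)

    def test_zero_threshold_is_identity(self, small_dataset):
        rep = {k: 0.0 for k in small_dataset.group_keys()}
        filtered, removed = exclude_low_representation(small_dataset, rep, 0.0)
        assert removed == [] and len(filtered) == len(small_dataset)

    def test_all_below_threshold_warns(self, small_dataset):
        rep = {k: 0.001 for k in small_dataset.group_keys()}
        with pytest.warns(ValidationWarning):
            filtered, removed = exclude_low_representation(small_dataset, rep)
        assert len(filtered) == 0 and len(removed) == 2

    def test_missing_group_raises(self, small_dataset):
        with pytest.raises(KeyError):
            exclude_low_representation(small_dataset, {}, 0.01)
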
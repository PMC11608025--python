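"""MTL, FiB and CTL: worked examples, closed forms, and brute-force oracles.

The oracles evaluate the printed formulas record-by-record in pure Python
(math.log10, explicit loops) and stay independent of the pandas
implementation they check.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trophodyn.exceptions import ConfigError, ValidationError
from trophodyn.indicators import (
    FiBParams,
    average_ctl,
    catch_share_series,
    compute_ctl,
    compute_fib,
    compute_mtl,
    rank_ctl,
)

from .conftest import make_catalog, make_catch

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_mtl(records, tl_map):
    """Σ TL_i·Y_ij / Σ Y_ij per year, by explicit loops."""
    per_year = {}
    for year, _, sid, catch in records:
        num, den = per_year.get(year, (0.0, 0.0))
        per_year[year] = (num + tl_map[sid] * catch, den + catch)
    return {y: num / den for y, (num, den) in per_year.items() if den > 0}


def oracle_fib(records, tl_map, te=0.10, baseline=None):
    """log10(Y_i (1/TE)^MTL_i) − log10(Y_0 (1/TE)^MTL_0), term by term."""
    mtl = oracle_mtl(records, tl_map)
    totals = {}
    for year, _, sid, catch in records:
        totals[year] = totals.get(year, 0.0) + catch
    baseline = min(totals) if baseline is None else baseline

    def term(y):
        return math.log10(totals[y] * (1.0 / te) ** mtl[y])

    return {y: term(y) - term(baseline) for y in totals if totals[y] > 0}


def oracle_ctl(records, tl_map):
    """TL_i·Y_ij / Σ TL_i·Y_ij × 100 per (year, species)."""
    denom = {}
    for year, _, sid, catch in records:
        denom[year] = denom.get(year, 0.0) + tl_map[sid] * catch
    out = {}
    for year, _, sid, catch in records:
        key = (year, sid)
        out[key] = out.get(key, 0.0) + 100.0 * tl_map[sid] * catch / denom[year]
    return out


def random_table(rng, n_species=3, n_years=5):
    species = [f"sp {chr(97 + i)}" for i in range(n_species)]
    tl_map = {s: rng.uniform(2.0, 4.5) for s in species}
    records = [
        (1970 + y, "offshore", s, rng.uniform(0.5, 1000.0))
        for y in range(n_years)
        for s in species
    ]
    catalog = make_catalog([(s, tl_map[s], "indigenous") for s in species])
    return make_catch(records), catalog, records, tl_map


# ---------------------------------------------------------------------------
# MTL
# ---------------------------------------------------------------------------


class TestMTL:
    def test_single_species_mtl_equals_its_tl(self):
        catalog = make_catalog([("solo fish", 4.0, "indigenous")])
        table = make_catch([(2000, "coastal", "solo fish", 123.0)])
        assert compute_mtl(table, catalog, "coastal").values[2000] == 4.0

    def test_equal_catches_average_the_tls(self):
        catalog = make_catalog([("lo", 3.0, "indigenous"), ("hi", 5.0, "indigenous")])
        table = make_catch(
            [(2000, "coastal", "lo", 7.0), (2000, "coastal", "hi", 7.0)]
        )
        assert compute_mtl(table, catalog, "coastal").values[2000] == pytest.approx(4.0)

    def test_weighted_mean_example(self):
        # (4.23*800 + 3.99*200) / 1000 = 4.182
        catalog = make_catalog([("mack", 4.23, "indigenous"), ("hair", 3.99, "indigenous")])
        table = make_catch(
            [(2000, "offshore", "mack", 800.0), (2000, "offshore", "hair", 200.0)]
        )
        assert compute_mtl(table, catalog, "offshore").values[2000] == pytest.approx(
            4.182, abs=1e-12
        )

    def test_species_without_tl_is_named_in_error(self, toy_catalog):
        table = make_catch([(2000, "coastal", "mystery fish", 1.0)])
        with pytest.raises(ValidationError, match="mystery fish"):
            compute_mtl(table, toy_catalog, "coastal")

    def test_zero_catch_year_is_missing(self):
        catalog = make_catalog([("solo fish", 4.0, "indigenous")])
        table = make_catch(
            [(2000, "coastal", "solo fish", 0.0), (2001, "coastal", "solo fish", 1.0)]
        )
        series = compute_mtl(table, catalog, "coastal").values
        assert 2000 not in series.index and 2001 in series.index

    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle(self, seed):
        table, catalog, records, tl_map = random_table(np.random.default_rng(seed))
        got = compute_mtl(table, catalog, "offshore").values
        want = oracle_mtl(records, tl_map)
        for year, val in want.items():
            assert got[year] == pytest.approx(val, abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.floats(1e-3, 1e3))
    def test_scale_invariant_and_bounded(self, seed, scale):
        table, catalog, _, tl_map = random_table(np.random.default_rng(seed))
        base = compute_mtl(table, catalog, "offshore").values
        scaled_table = table.assign(catch=table["catch"] * scale)
        scaled = compute_mtl(scaled_table, catalog, "offshore").values
        assert np.allclose(base.to_numpy(), scaled.to_numpy(), atol=1e-9)
        assert (base >= min(tl_map.values()) - 1e-12).all()
        assert (base <= max(tl_map.values()) + 1e-12).all()

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        table, catalog, _, _ = random_table(rng)
        shuffled = table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = compute_mtl(table, catalog, "offshore").values
        b = compute_mtl(shuffled, catalog, "offshore").values
        pd.testing.assert_series_equal(a, b)


# ---------------------------------------------------------------------------
# FiB
# ---------------------------------------------------------------------------


class TestFiB:
    def test_baseline_year_is_exactly_zero(self):
        table, catalog, _, _ = random_table(np.random.default_rng(0))
        fib = compute_fib(table, catalog, "offshore", FiBParams(baseline_year=1970))
        assert fib.values[1970] == 0.0

    def test_doubled_catch_at_constant_mtl_gains_log10_2(self):
        catalog = make_catalog([("solo fish", 4.0, "indigenous")])
        table = make_catch(
            [(1970, "coastal", "solo fish", 50.0), (1971, "coastal", "solo fish", 100.0)]
        )
        fib = compute_fib(table, catalog, "coastal", FiBParams(baseline_year=1970))
        assert fib.values[1971] == pytest.approx(math.log10(2.0), abs=1e-12)

    def test_one_level_mtl_drop_compensated_by_tenfold_catch(self):
        """At TE = 0.1 a one-level MTL drop with a ten-fold catch rise keeps FiB flat."""
        catalog = make_catalog([("hi", 4.0, "indigenous"), ("lo", 3.0, "indigenous")])
        table = make_catch(
            [(1970, "coastal", "hi", 10.0), (1971, "coastal", "lo", 100.0)]
        )
        fib = compute_fib(table, catalog, "coastal", FiBParams(baseline_year=1970))
        assert fib.values[1971] == pytest.approx(0.0, abs=1e-12)

    def test_missing_baseline_year_is_a_config_error(self):
        catalog = make_catalog([("solo fish", 4.0, "indigenous")])
        table = make_catch([(1990, "coastal", "solo fish", 1.0)])
        with pytest.raises(ConfigError, match="1970"):
            compute_fib(table, catalog, "coastal", FiBParams(baseline_year=1970))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle(self, seed):
        table, catalog, records, tl_map = random_table(np.random.default_rng(seed))
        got = compute_fib(table, catalog, "offshore", FiBParams(baseline_year=1970))
        want = oracle_fib(records, tl_map, te=0.10, baseline=1970)
        for year, val in want.items():
            assert got.values[year] == pytest.approx(val, abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.floats(1e-3, 1e3))
    def test_scale_invariant(self, seed, scale):
        """A global catch rescaling cancels between year i and the baseline."""
        table, catalog, _, _ = random_table(np.random.default_rng(seed))
        params = FiBParams(baseline_year=1970)
        base = compute_fib(table, catalog, "offshore", params).values
        scaled = compute_fib(
            table.assign(catch=table["catch"] * scale), catalog, "offshore", params
        ).values
        assert np.allclose(base.to_numpy(), scaled.to_numpy(), atol=1e-9)


# ---------------------------------------------------------------------------
# CTL
# ---------------------------------------------------------------------------


class TestCTL:
    def test_single_species_takes_100_percent(self):
        catalog = make_catalog([("solo fish", 4.0, "indigenous")])
        table = make_catch(
            [(2000, "coastal", "solo fish", 5.0), (2001, "coastal", "solo fish", 9.0)]
        )
        ctl = compute_ctl(table, catalog)
        assert (ctl.annual["solo fish"] == 100.0).all()

    def test_constructed_tie_splits_evenly(self):
        # TL 4 × catch 1 and TL 2 × catch 2 both weigh 4
        catalog = make_catalog([("a", 4.0, "indigenous"), ("b", 2.0, "indigenous")])
        table = make_catch([(2000, "coastal", "a", 1.0), (2000, "coastal", "b", 2.0)])
        ctl = compute_ctl(table, catalog)
        assert ctl.annual.loc[2000, "a"] == pytest.approx(50.0)
        assert ctl.annual.loc[2000, "b"] == pytest.approx(50.0)

    def test_weighted_shares_example(self):
        # products 12 and 2 → 12/14 and 2/14
        catalog = make_catalog([("a", 4.0, "indigenous"), ("b", 2.0, "indigenous")])
        table = make_catch([(2000, "coastal", "a", 3.0), (2000, "coastal", "b", 1.0)])
        ctl = compute_ctl(table, catalog)
        assert ctl.annual.loc[2000, "a"] == pytest.approx(100 * 12 / 14, abs=1e-9)
        assert ctl.annual.loc[2000, "b"] == pytest.approx(100 * 2 / 14, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle_and_sums_to_100(self, seed):
        table, catalog, records, tl_map = random_table(np.random.default_rng(seed))
        ctl = compute_ctl(table, catalog, sector="offshore")
        want = oracle_ctl(records, tl_map)
        for (year, sid), val in want.items():
            assert ctl.annual.loc[year, sid] == pytest.approx(val, abs=1e-12)
        assert np.allclose(ctl.annual.sum(axis=1).to_numpy(), 100.0, rtol=1e-9)

    def test_absent_species_year_is_zero_percent(self):
        catalog = make_catalog([("a", 4.0, "indigenous"), ("b", 2.0, "indigenous")])
        table = make_catch(
            [
                (2000, "coastal", "a", 1.0),
                (2000, "coastal", "b", 1.0),
                (2001, "coastal", "a", 1.0),
            ]
        )
        ctl = compute_ctl(table, catalog)
        assert ctl.annual.loc[2001, "b"] == 0.0


class TestAverageCTL:
    def test_constant_100_averages_to_100(self):
        catalog = make_catalog([("solo fish", 4.0, "indigenous")])
        table = make_catch([(y, "coastal", "solo fish", 1.0) for y in range(2000, 2010)])
        avg = average_ctl(compute_ctl(table, catalog))
        assert avg["solo fish"] == pytest.approx(100.0)

    def test_absence_years_count_as_zero(self):
        # 50% in half the years, absent otherwise → period mean 25%
        catalog = make_catalog(
            [("a", 3.0, "indigenous"), ("b", 3.0, "indigenous"), ("c", 3.0, "indigenous")]
        )
        records = []
        for y in (2000, 2001):
            records += [(y, "coastal", "a", 1.0), (y, "coastal", "b", 1.0)]
        for y in (2002, 2003):
            records += [(y, "coastal", "c", 1.0)]
        avg = average_ctl(compute_ctl(make_catch(records), catalog), (2000, 2003))
        assert avg["a"] == pytest.approx(25.0)

    def test_presence_only_mode(self):
        catalog = make_catalog(
            [("a", 3.0, "indigenous"), ("b", 3.0, "indigenous"), ("c", 3.0, "indigenous")]
        )
        records = [(2000, "coastal", "a", 1.0), (2000, "coastal", "b", 1.0)]
        records += [(2001, "coastal", "c", 1.0)]
        avg = average_ctl(
            compute_ctl(make_catch(records), catalog), absent_as_zero=False
        )
        assert avg["a"] == pytest.approx(50.0)

    def test_empty_or_out_of_range_window_rejected(self):
        catalog = make_catalog([("a", 3.0, "indigenous")])
        ctl = compute_ctl(make_catch([(2000, "coastal", "a", 1.0)]), catalog)
        with pytest.raises(ValueError):
            average_ctl(ctl, (2001, 2000))
        with pytest.raises(ValueError):
            average_ctl(ctl, (1990, 2000))


class TestRankAndShares:
    def test_rank_takes_top_k_descending(self):
        avg = pd.Series({"a": 30.0, "b": 10.0})
        ranked = rank_ctl(avg, 1)
        assert list(ranked.index) == ["a"]
        assert ranked["cumulative_percent"].iloc[-1] == 30.0

    def test_rank_ties_alphabetical(self):
        ranked = rank_ctl(pd.Series({"zeta": 10.0, "alpha": 10.0}), 2)
        assert list(ranked.index) == ["alpha", "zeta"]

    def test_rank_k_exceeding_length_returns_all(self):
        assert len(rank_ctl(pd.Series({"a": 1.0, "b": 2.0}), 10)) == 2

    def test_rank_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            rank_ctl(pd.Series({"a": 1.0}), 0)

    def test_single_retained_species_holds_100_percent(self):
        table = make_catch([(2000, "coastal", "a", 3.0)])
        shares = catch_share_series(table, "coastal")
        assert shares.loc[2000, "a"] == 100.0

    def test_share_of_annual_total(self):
        table = make_catch(
            [(2000, "coastal", "a", 20.0), (2000, "coastal", "b", 80.0)]
        )
        shares = catch_share_series(table, "coastal", ["a"])
        assert shares.loc[2000, "a"] == pytest.approx(20.0)

    @given(st.integers(0, 2**31 - 1))
    def test_shares_sum_to_100_over_all_retained_species(self, seed):
        table, _, _, _ = random_table(np.random.default_rng(seed))
        shares = catch_share_series(table, "offshore")
        assert np.allclose(shares.sum(axis=1).to_numpy(), 100.0, rtol=1e-9)
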
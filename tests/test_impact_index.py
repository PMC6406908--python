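"""AI / AII computation and Δ-AII fold changes with zero substitution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minerva import (
    AIITable,
    JournalSpec,
    SUB_CONSTANT_DEFAULT,
    ValidationError,
    annual_impact,
    annual_impact_index,
    compute_aii_table,
    delta_aii,
    derive_sub_constant,
    read_aii_csv,
    read_delta_csv,
    write_aii_csv,
    write_delta_csv,
)
from conftest import random_panel


def aii_oracle(panel):
    """Independent nested-loop recomputation of the AII table."""
    out = np.zeros((len(panel.fields), len(panel.years)))
    for fi, f in enumerate(panel.fields):
        for yi, y in enumerate(panel.years):
            total = 0.0
            for ji, j in enumerate(panel.journals):
                total += panel.counts[fi, ji, yi] * j.impact_factor
            out[fi, yi] = total
    return out


class TestAnnualImpact:
    @pytest.mark.parametrize(
        "count, impact, expected",
        [(6, 40.137, 240.822), (2, 44.405, 88.81), (1, 37.205, 37.205), (0, 40.137, 0.0), (1, 1.081, 1.081)],
    )
    def test_worked_examples(self, count, impact, expected):
        assert annual_impact(count, impact) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("count, impact", [(-1, 2.0), (1.5, 2.0), (1, 0.0), (1, -3.0)])
    def test_domain_errors(self, count, impact):
        with pytest.raises(ValueError):
            annual_impact(count, impact)


class TestAnnualImpactIndex:
    def test_hand_sum(self, small_panel):
        # glioma 2015: 2*40.137 + 0*44.405 + 5*1.081
        assert annual_impact_index(small_panel, "glioma", 2015) == pytest.approx(
            2 * 40.137 + 5 * 1.081
        )

    def test_single_article_single_journal(self, small_panel):
        # epigenetics 2017: one article in Nature only
        assert annual_impact_index(small_panel, "epigenetics", 2017) == pytest.approx(40.137)

    def test_all_zero_year_is_zero(self, journals):
        from minerva import CountPanel, FieldSpec

        panel = CountPanel(
            fields=[FieldSpec("f")],
            journals=journals,
            years=range(2010, 2012),
            counts=np.zeros((1, 3, 2), dtype=int),
        )
        assert annual_impact_index(panel, "f", 2010) == 0.0

    def test_unknown_lookups_raise(self, small_panel):
        with pytest.raises(KeyError):
            annual_impact_index(small_panel, "nope", 2015)
        with pytest.raises(KeyError):
            annual_impact_index(small_panel, "glioma", 1999)


class TestComputeAiiTable:
    def test_matches_nested_loop_oracle_on_random_panels(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            panel = random_panel(rng, n_fields=int(rng.integers(1, 10)),
                                 n_journals=int(rng.integers(1, 10)),
                                 n_years=int(rng.integers(2, 10)))
            table = compute_aii_table(panel)
            np.testing.assert_allclose(table.values, aii_oracle(panel), rtol=1e-9)

    def test_journal_permutation_invariance(self, small_panel):
        from minerva import CountPanel

        perm = [2, 0, 1]
        permuted = CountPanel(
            fields=small_panel.fields,
            journals=[small_panel.journals[i] for i in perm],
            years=small_panel.years,
            counts=small_panel.counts[:, perm, :],
        )
        np.testing.assert_allclose(
            compute_aii_table(permuted).values, compute_aii_table(small_panel).values
        )

    def test_additivity_over_journal_partition(self):
        """AII of a panel is the sum of AIIs over any split of its journals."""
        from minerva import CountPanel

        rng = np.random.default_rng(7)
        panel = random_panel(rng, n_journals=6)
        half_a = CountPanel(panel.fields, panel.journals[:3], panel.years, panel.counts[:, :3, :])
        half_b = CountPanel(panel.fields, panel.journals[3:], panel.years, panel.counts[:, 3:, :])
        np.testing.assert_allclose(
            compute_aii_table(panel).values,
            compute_aii_table(half_a).values + compute_aii_table(half_b).values,
            rtol=1e-12,
        )

    @given(c=st.floats(min_value=0.01, max_value=100.0, allow_nan=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_homogeneity_in_impact_factors(self, c):
        """Scaling every IF by c scales every AII by c and cancels in Δ-AII."""
        from minerva import CountPanel

        rng = np.random.default_rng(11)
        panel = random_panel(rng)
        scaled = CountPanel(
            panel.fields,
            [JournalSpec(j.name, j.impact_factor * c) for j in panel.journals],
            panel.years,
            panel.counts,
        )
        t0, t1 = compute_aii_table(panel), compute_aii_table(scaled)
        np.testing.assert_allclose(t1.values, c * t0.values, rtol=1e-9)
        d0, d1 = delta_aii(t0), delta_aii(t1)
        if not d0.substituted and not d1.substituted:
            np.testing.assert_allclose(d1.values, d0.values, rtol=1e-9)


class TestDeltaAii:
    def test_worked_fold_changes(self):
        table = AIITable(
            fields=("epigenetics", "glioblastoma"),
            years=range(2012, 2014),
            values=np.array([[15.760, 88.141], [3298.539, 3972.712]]),
        )
        series = delta_aii(table)
        assert round(series.value("epigenetics", 2013), 3) == 5.593
        assert round(series.value("glioblastoma", 2013), 3) == 1.204
        assert not series.substituted

    def test_zero_to_zero_reads_as_no_change(self):
        table = AIITable(fields=("f",), years=range(2010, 2012), values=np.array([[0.0, 0.0]]))
        series = delta_aii(table)
        assert series.value("f", 2011) == pytest.approx(1.0)
        positions = {(s.year, s.position) for s in series.substituted}
        assert positions == {(2011, "numerator"), (2011, "denominator")}

    def test_zero_denominator_substitution(self):
        table = AIITable(fields=("f",), years=range(2010, 2012), values=np.array([[0.0, 88.141]]))
        series = delta_aii(table)
        assert series.value("f", 2011) == pytest.approx(88.141 / 1.081)
        assert {s.position for s in series.substituted} == {"denominator"}

    def test_constant_series_is_unit_fold_change(self):
        table = AIITable(fields=("f",), years=range(2010, 2015), values=np.full((1, 5), 7.7))
        np.testing.assert_allclose(delta_aii(table).values, 1.0)

    def test_unsubstituted_entries_reconstruct_the_ratio(self):
        rng = np.random.default_rng(5)
        panel = random_panel(rng, n_fields=6)
        table = compute_aii_table(panel)
        series = delta_aii(table)
        subbed = {(s.field, s.year) for s in series.substituted}
        for fi, f in enumerate(series.fields):
            for y in series.years:
                if (f, y) not in subbed:
                    assert series.value(f, y) * table.value(f, y - 1) == pytest.approx(
                        table.value(f, y), rel=1e-9
                    )

    def test_positivity_and_finiteness(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            table = compute_aii_table(random_panel(rng, n_fields=3, n_journals=2))
            vals = delta_aii(table).values
            assert np.isfinite(vals).all() and (vals > 0).all()

    def test_bad_configuration_rejected(self):
        table = AIITable(fields=("f",), years=range(2010, 2012), values=np.array([[1.0, 2.0]]))
        with pytest.raises(ValidationError):
            delta_aii(table, sub_constant=0.0)
        short = AIITable(fields=("f",), years=range(2010, 2011), values=np.array([[1.0]]))
        with pytest.raises(ValidationError):
            delta_aii(short)

    def test_default_constant_derives_from_lowest_if_journal(self, journals):
        assert SUB_CONSTANT_DEFAULT == 1.081
        assert derive_sub_constant(journals) == 1.081


class TestCsvRoundTrips:
    def test_aii_table(self, tmp_path, small_panel):
        table = compute_aii_table(small_panel)
        p = tmp_path / "aii.csv"
        write_aii_csv(table, p)
        back = read_aii_csv(p)
        assert back.fields == table.fields and back.years == table.years
        np.testing.assert_allclose(back.values, table.values)

    def test_delta_series_with_substitutions(self, tmp_path):
        table = AIITable(
            fields=("a", "b"),
            years=range(2010, 2013),
            values=np.array([[0.0, 2.0, 0.0], [1.0, 1.0, 3.0]]),
        )
        series = delta_aii(table)
        p = tmp_path / "delta.csv"
        write_delta_csv(series, p)
        back = read_delta_csv(p)
        np.testing.assert_allclose(back.values, series.values)
        assert back.substituted == series.substituted
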
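"""Cell-type records, bespoke turnover estimators, and table I/O."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cfflux.turnover import (
    CellTypeRecord,
    CellTypeTableError,
    PloidyGroup,
    combine_estimates,
    hepatocyte_turnover,
    load_celltype_table,
    mk_turnover_from_marrow,
    mk_turnover_from_platelets,
    save_celltype_table,
)
from cfflux.uncertainty import make_lognormal


class TestRecordInvariants:
    def test_valid_record(self):
        r = CellTypeRecord("erythrocyte_progenitors", make_lognormal(2e11, 1.3))
        assert r.ploidy == 2.0 and r.measured_fraction is None

    def test_shed_with_fraction_rejected(self):
        with pytest.raises(ValueError, match="shed"):
            CellTypeRecord(
                "gut_epithelium",
                make_lognormal(1e10),
                shed_externally=True,
                measured_fraction=make_lognormal(0.1),
            )

    @pytest.mark.parametrize("fraction", [1.5, 2.0])
    def test_fraction_above_one_rejected(self, fraction):
        with pytest.raises(ValueError, match="fraction"):
            CellTypeRecord("x", make_lognormal(1e9), measured_fraction=make_lognormal(fraction))

    def test_subhaploid_ploidy_rejected(self):
        with pytest.raises(ValueError, match="ploidy"):
            CellTypeRecord("x", make_lognormal(1e9), ploidy=0.5)


class TestMegakaryocyteEstimators:
    def test_marrow_route(self):
        t = mk_turnover_from_marrow(make_lognormal(1e10), make_lognormal(5))
        assert t.median == pytest.approx(2e9)
        assert t.factor == 1.0

    def test_platelet_route(self):
        t = mk_turnover_from_platelets(make_lognormal(1e11), make_lognormal(2000))
        assert t.median == pytest.approx(5e7)

    def test_exact_divisor_preserves_factor(self):
        t = mk_turnover_from_marrow(make_lognormal(1e10, 2), make_lognormal(5))
        assert t.factor == pytest.approx(2.0)

    def test_shape_rule_through_division(self):
        t = mk_turnover_from_marrow(make_lognormal(1e10, 1.5), make_lognormal(5, 1.5))
        assert t.factor == pytest.approx(math.exp(math.sqrt(2) * math.log(1.5)), rel=1e-12)
        both_f2 = mk_turnover_from_platelets(make_lognormal(1e11, 2), make_lognormal(2000, 2))
        assert both_f2.factor == pytest.approx(2 ** math.sqrt(2), rel=1e-12)

    @given(
        st.floats(min_value=1e8, max_value=1e12),
        st.floats(min_value=1.0, max_value=30.0),
        st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_homogeneity(self, n, t, k):
        # degree +1 in the numerator, -1 in the denominator
        base = mk_turnover_from_marrow(make_lognormal(n), make_lognormal(t))
        up = mk_turnover_from_marrow(make_lognormal(n * k), make_lognormal(t))
        down = mk_turnover_from_marrow(make_lognormal(n), make_lognormal(t * k))
        assert up.median == pytest.approx(base.median * k, rel=1e-9)
        assert down.median == pytest.approx(base.median / k, rel=1e-9)


class TestHepatocytes:
    def test_flux_weighted_combination(self):
        groups = [PloidyGroup(1e11, 0.002, 2), PloidyGroup(5e10, 0.001, 4)]
        turnover, ploidy = hepatocyte_turnover(groups)
        assert turnover.median == pytest.approx(2.5e8)
        assert ploidy == pytest.approx(2.4)

    def test_single_group(self):
        turnover, ploidy = hepatocyte_turnover([PloidyGroup(1e10, 0.003, 4)])
        assert turnover.median == pytest.approx(3e7)
        assert ploidy == 4

    def test_equal_fluxes_symmetric(self):
        groups = [PloidyGroup(1e10, 0.002, 2), PloidyGroup(2e10, 0.001, 4)]
        _, ploidy = hepatocyte_turnover(groups)
        assert ploidy == pytest.approx(3.0)

    @given(
        st.lists(
            st.builds(
                PloidyGroup,
                st.floats(min_value=1e8, max_value=1e12),
                st.floats(min_value=1e-4, max_value=0.05),
                st.sampled_from([2.0, 4.0, 8.0]),
            ),
            min_size=1,
            max_size=5,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_effective_ploidy_bounded(self, groups):
        _, ploidy = hepatocyte_turnover(groups)
        ploidies = [g.ploidy for g in groups]
        assert min(ploidies) - 1e-9 <= ploidy <= max(ploidies) + 1e-9

    def test_group_uncertainty_widens_result(self):
        groups = [PloidyGroup(1e11, 0.002, 2), PloidyGroup(5e10, 0.001, 4)]
        noisy, _ = hepatocyte_turnover(groups, flux_factor=1.8, seed=4)
        assert noisy.median == pytest.approx(2.5e8)
        assert 1.3 < noisy.factor < 1.9  # sum averages some of the spread away

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hepatocyte_turnover([])


class TestCombineEstimates:
    def test_identical_estimates_unchanged(self):
        a = make_lognormal(2e9, 1.4)
        merged = combine_estimates(a, a)
        assert merged.median == pytest.approx(2e9)
        assert merged.factor == pytest.approx(1.4)

    def test_disagreement_inflates_factor(self):
        merged = combine_estimates(make_lognormal(1e9), make_lognormal(4e9))
        assert merged.median == pytest.approx(2e9)
        assert merged.factor == pytest.approx(2.0)

    def test_large_within_factor_retained(self):
        a = make_lognormal(1e9, 3)
        assert combine_estimates(a, a).factor == pytest.approx(3.0)

    def test_unit_mismatch(self):
        with pytest.raises(ValueError, match="units"):
            combine_estimates(
                make_lognormal(1), make_lognormal(1), unit_a="cells/day", unit_b="cells/h"
            )


class TestTableIO:
    def test_roundtrip(self, tmp_path, reference_records):
        out = tmp_path / "table.csv"
        save_celltype_table(reference_records, out)
        back = load_celltype_table(out)
        assert back == reference_records

    def test_reference_table_content(self, reference_records):
        by_name = {r.name: r for r in reference_records}
        ery = by_name["erythrocyte_progenitors"]
        assert ery.turnover.median == pytest.approx(2e11)
        assert not ery.shed_externally and ery.measured_fraction is not None
        shed = [r for r in reference_records if r.shed_externally]
        assert shed and all(r.measured_fraction is None for r in shed)
        fractions = [
            r.measured_fraction.median
            for r in reference_records
            if r.measured_fraction is not None
        ]
        assert sum(fractions) <= 1.0

    def test_invalid_row_reports_row_number(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text(
            "name,turnover_median,turnover_factor,ploidy,shed_externally,"
            "fraction_median,fraction_factor\n"
            "ok_type,1e9,1.5,2,false,,\n"
            "gut,1e10,1.5,2,true,0.1,1.5\n"
        )
        with pytest.raises(CellTypeTableError, match="row 3"):
            load_celltype_table(bad)

    def test_missing_column(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("name,turnover_median\nx,1e9\n")
        with pytest.raises(CellTypeTableError, match="missing columns"):
            load_celltype_table(bad)

    def test_empty_table_warns(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text(",".join(
            ["name", "turnover_median", "turnover_factor", "ploidy",
             "shed_externally", "fraction_median", "fraction_factor"]) + "\n")
        with pytest.warns(UserWarning, match="empty"):
            assert load_celltype_table(empty) == []

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_celltype_table(tmp_path / "nope.csv")
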
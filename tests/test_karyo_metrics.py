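import numpy as np
import pytest
from hypothesis import given, strategies as st

from karyoevol import (
    BaseNumberRecord,
    ChromosomeMeasurement,
    KaryotypeRecord,
    asymmetry_index,
    build_karyotype,
    classify_chromosome,
    parse_formula,
    render_formula,
    tally_base_numbers,
)
from karyoevol.karyo_metrics import KaryotypeError
from karyoevol.synthetic import simulate_karyotype_measurements


class TestClassify:
    @pytest.mark.parametrize(
        "long_um,short_um,expected",
        [
            (5.0, 5.0, "m"),  # r = 1
            (1.7, 1.0, "m"),  # boundary belongs to the more symmetric class
            (7.0, 3.0, "sm"),  # r = 2.33
            (3.0, 1.0, "sm"),  # boundary
            (6.0, 1.0, "st"),  # r = 6
            (7.0, 1.0, "st"),  # boundary
            (8.0, 1.0, "t"),  # r = 8
        ],
    )
    def test_levan_classes(self, long_um, short_um, expected):
        assert classify_chromosome(long_um, short_um) == expected

    def test_nonpositive_arm_rejected(self):
        with pytest.raises(KaryotypeError):
            classify_chromosome(5.0, 0.0)

    def test_swapped_arms_handled(self):
        assert classify_chromosome(1.0, 8.0) == "t"

    @given(st.floats(min_value=1.0, max_value=50.0), st.floats(min_value=0.0, max_value=5.0))
    def test_monotone_in_arm_ratio(self, r, dr):
        order = ["m", "sm", "st", "t"]
        a = order.index(classify_chromosome(r, 1.0))
        b = order.index(classify_chromosome(r + dr, 1.0))
        assert b >= a


class TestFormula:
    def test_render_omits_zero_classes(self):
        s = render_formula(6, 2, {"m": 2, "sm": 2, "st": 2})
        assert s == "2n = 2x = 6 = 2m + 2sm + 2st"

    def test_render_checks_sum(self):
        with pytest.raises(KaryotypeError):
            render_formula(6, 2, {"m": 2})

    @given(
        st.integers(min_value=0, max_value=6),
        st.integers(min_value=0, max_value=6),
        st.integers(min_value=0, max_value=6),
        st.integers(min_value=0, max_value=6),
    )
    def test_parse_inverts_render(self, m, sm, st_, t):
        counts = {k: 2 * v for k, v in zip(("m", "sm", "st", "t"), (m, sm, st_, t)) if v}
        two_n = sum(counts.values())
        if two_n == 0:
            return
        s = render_formula(two_n, 2, counts)
        assert parse_formula(s) == (two_n, 2, counts)


def _uniform_cells(n_cells=10):
    """3 pairs per cell with (m, sm, st) morphology, no noise."""
    out = []
    templates = [(6.0, 5.0), (5.5, 2.75), (4.0, 1.0)]  # r = 1.2, 2, 4
    for cell in range(n_cells):
        k = 0
        for long_um, short_um in templates:
            for _ in range(2):
                k += 1
                out.append(
                    ChromosomeMeasurement(f"c{cell}", f"chr{k}", long_um, short_um)
                )
    return out


class TestBuildKaryotype:
    def test_formula_rendering(self):
        rec = build_karyotype(_uniform_cells(), two_n=6, ploidy=2, taxon="toy")
        assert rec.formula == "2n = 2x = 6 = 2m + 2sm + 2st"
        assert rec.base_number == 3

    def test_zacintha_style_formula(self):
        # haploid set (m, sm, sm) doubles to 2m + 4sm
        out = []
        templates = [(6.0, 5.0), (5.0, 2.5), (4.0, 2.0)]
        for cell in range(10):
            k = 0
            for long_um, short_um in templates:
                for _ in range(2):
                    k += 1
                    out.append(ChromosomeMeasurement(f"c{cell}", f"chr{k}", long_um, short_um))
        rec = build_karyotype(out, two_n=6, ploidy=2)
        assert rec.formula == "2n = 2x = 6 = 2m + 4sm"

    def test_simulation_round_trip_with_noise(self):
        ms = simulate_karyotype_measurements(
            "2n = 2x = 10 = 4m + 4sm + 2st", n_cells=10, noise_cv=2.0, seed=7
        )
        rec = build_karyotype(ms, two_n=10, ploidy=2)
        assert rec.formula == "2n = 2x = 10 = 4m + 4sm + 2st"

    def test_wrong_cell_size_names_cell(self):
        ms = _uniform_cells()[:-1]  # drop one chromosome from the last cell
        with pytest.raises(KaryotypeError, match="c9"):
            build_karyotype(ms, two_n=6)

    def test_few_cells_warns_but_succeeds(self):
        with pytest.warns(UserWarning, match="cells"):
            rec = build_karyotype(_uniform_cells(2), two_n=6)
        assert rec.n_cells == 2

    def test_class_counts_sum_to_two_n(self):
        rec = build_karyotype(_uniform_cells(), two_n=6)
        assert sum(rec.class_counts.values()) == rec.two_n


class TestAsymmetryIndex:
    def test_uniform_karyotype_has_zero_ai(self):
        rec = KaryotypeRecord(
            taxon="t", two_n=4, ploidy=2,
            lengths_um=[10.0, 10.0, 10.0, 10.0],
            centromeric_indices=[50.0, 50.0, 50.0, 50.0],
            classes=["m"] * 4,
        )
        cv_cl, cv_ci, ai = asymmetry_index(rec)
        assert cv_cl == 0.0 and ai == 0.0

    def test_hand_computed_example(self):
        # chromosomes (6,4), (4.8,3.2), (3,3): lengths 10, 8, 6; CIs 40, 40, 50
        rec = KaryotypeRecord(
            taxon="t", two_n=2, ploidy=1,
            lengths_um=[10.0, 8.0],
            centromeric_indices=[40.0, 40.0],
            classes=["m", "m"],
        )
        # build the 3-chromosome case directly on the arrays
        lengths = np.array([10.0, 8.0, 6.0])
        cis = np.array([40.0, 40.0, 50.0])
        cv_cl = 100 * np.std(lengths, ddof=1) / lengths.mean()
        cv_ci = 100 * np.std(cis, ddof=1) / cis.mean()
        assert cv_cl == pytest.approx(25.0, abs=1e-9)
        assert cv_ci == pytest.approx(13.3235, abs=1e-4)
        assert cv_cl * cv_ci / 100 == pytest.approx(3.331, abs=5e-4)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, factor):
        lengths = [10.0, 8.0, 6.0, 5.0]
        cis = [40.0, 35.0, 50.0, 45.0]
        base = KaryotypeRecord("t", 4, 2, lengths, cis, ["m"] * 4)
        scaled = KaryotypeRecord(
            "t", 4, 2, [x * factor for x in lengths], cis, ["m"] * 4
        )
        assert asymmetry_index(scaled)[2] == pytest.approx(
            asymmetry_index(base)[2], rel=1e-9
        )

    def test_single_chromosome_rejected(self):
        rec = KaryotypeRecord("t", 2, 2, [10.0, 9.0], [50.0, 50.0], ["m", "m"])
        rec.lengths_um = np.array([10.0])
        rec.centromeric_indices = np.array([50.0])
        with pytest.raises(KaryotypeError):
            asymmetry_index(rec)


class TestTally:
    def test_empty(self):
        assert tally_base_numbers([]) == {}

    def test_accessions_collapse(self):
        recs = [
            BaseNumberRecord("Crepis aurea", 4),
            BaseNumberRecord("Crepis aurea", 4),
        ]
        assert tally_base_numbers(recs) == {4: 1}

    def test_infraspecific_merging_toggle(self):
        recs = [
            BaseNumberRecord("Crepis foetida", 5, infraspecific=""),
            BaseNumberRecord("Crepis foetida", 5, infraspecific="rhoaedifolia"),
        ]
        assert tally_base_numbers(recs, merge_infraspecific=True) == {5: 1}
        assert tally_base_numbers(recs, merge_infraspecific=False) == {5: 2}

    def test_conflicting_base_numbers_warn_and_count_each(self):
        recs = [
            BaseNumberRecord("Crepis mixta", 4),
            BaseNumberRecord("Crepis mixta", 5),
        ]
        with pytest.warns(UserWarning, match="conflicting"):
            assert tally_base_numbers(recs) == {4: 1, 5: 1}
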
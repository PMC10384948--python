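"""Peak-list parsing, mass arithmetic, annotation and join alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyrosig.errors import DomainError, FormatError, ValidationError
from thyrosig.feature_tables import (
    PROTON_MASS,
    CompoundRecord,
    Feature,
    Peak,
    PeakList,
    annotate,
    join_align,
    merge_modes,
    monoisotopic_mass,
    neutral_mass_from_mz,
    read_feature_table,
    read_peak_list,
)

# hand-summed from fixed atomic masses (C=12 exactly, H=1.00782503,
# O=15.99491462, P=30.97376163)
H2O_MASS = 2 * 1.00782503 + 15.99491462
EGC_MASS = 15 * 12 + 14 * 1.00782503 + 7 * 15.99491462           # C15H14O7
PHOSPHO_TRIESTER_MASS = (
    11 * 12 + 3 * 1.00782503 + 13 * 15.99491462 + 3 * 30.97376163  # C11H3O13P3
)


class TestPeakListIO:
    def test_well_formed_csv_parses_row_order(self, tmp_path):
        path = tmp_path / "run.csv"
        path.write_text("mz,rt_min,intensity\n100.5,1.2,5e4\n200.1,3.4,2e4\n99.9,0.5,1e3\n")
        pl = read_peak_list(path, run_id="S1", role="sample", mode="positive",
                            class_label="benign")
        assert len(pl) == 3
        assert [p.mz for p in pl.peaks] == [100.5, 200.1, 99.9]

    def test_header_only_csv_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("mz,rt_min,intensity\n")
        assert len(read_peak_list(path, "S1", "sample", "positive")) == 0

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("mz,intensity\n100.0,1e4\n")
        with pytest.raises(FormatError, match="rt_min"):
            read_peak_list(path, "S1", "sample", "positive")

    def test_negative_intensity_reports_row(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text("mz,rt_min,intensity\n100.0,1.0,5e4\n101.0,1.0,-3.0\n")
        with pytest.raises(ValidationError, match="row 1"):
            read_peak_list(path, "S1", "sample", "positive")

    def test_blank_run_rejects_class_label(self):
        with pytest.raises(ValidationError):
            PeakList(run_id="B1", role="blank", mode="positive",
                     class_label="benign")

    def test_feature_table_round_trips_through_csv(self, aligned_fixture, tmp_path):
        table, _, _ = aligned_fixture
        sub = table.select_features(np.arange(25))
        sub.write_csv(tmp_path / "table.csv")
        back = read_feature_table(tmp_path / "table.csv")
        np.testing.assert_allclose(back.intensities, sub.intensities)
        assert back.feature_ids == sub.feature_ids
        assert [s.run_id for s in back.samples] == [s.run_id for s in sub.samples]


class TestMassArithmetic:
    @pytest.mark.parametrize(
        "formula, expected, tol",
        [
            ("H2O", H2O_MASS, 1e-6),
            ("C15H14O7", EGC_MASS, 1e-3),
            ("C11H3O13P3", PHOSPHO_TRIESTER_MASS, 1e-3),
        ],
    )
    def test_monoisotopic_mass_matches_hand_sum(self, formula, expected, tol):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=tol)

    def test_unknown_element_is_a_parse_error(self):
        with pytest.raises(FormatError):
            monoisotopic_mass("C2Xx3")

    def test_neutral_mass_positive_mode(self):
        # epigallocatechin [M+H]+ observed at 307.083
        assert neutral_mass_from_mz(307.083, "positive") == pytest.approx(
            306.0758, abs=1e-3
        )

    def test_neutral_mass_negative_mode(self):
        assert neutral_mass_from_mz(434.872, "negative") == pytest.approx(
            435.8793, abs=1e-3
        )

    def test_zero_neutral_mass_is_domain_error(self):
        with pytest.raises(DomainError):
            neutral_mass_from_mz(PROTON_MASS, "positive")

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=50.0, max_value=1500.0))
    def test_adduct_round_trip(self, mass):
        assert neutral_mass_from_mz(mass + PROTON_MASS, "positive") == pytest.approx(
            mass, abs=1e-9
        )


class TestAnnotation:
    def test_epigallocatechin_match_and_ppm_sign(self):
        feat = Feature("f1", "positive", 307.083, 2.56)
        comp = CompoundRecord("HMDB0038361", "(-)-Epigallocatechin", "C15H14O7",
                              monoisotopic_mass("C15H14O7"))
        anns = annotate([feat], [comp], tol_ppm=15)
        assert len(anns) == 1
        assert anns[0].ppm_error == pytest.approx(5.8, abs=0.3)
        assert anns[0].adduct == "[M+H]+"

    def test_beyond_tolerance_is_empty(self):
        feat = Feature("f1", "positive", 307.083, 2.56)
        off = 306.0758 * (1 + 20e-6)
        comp = CompoundRecord("X", "x", "", off)
        assert annotate([feat], [comp], tol_ppm=15) == []

    def test_identical_mass_gives_zero_ppm(self):
        mass = 306.0758
        feat = Feature("f1", "positive", mass + PROTON_MASS, 2.0)
        comp = CompoundRecord("X", "x", "", mass)
        anns = annotate([feat], [comp])
        assert anns[0].ppm_error == pytest.approx(0.0, abs=1e-9)

    def test_multiple_matches_sorted_by_abs_ppm(self):
        mass = 400.0
        feat = Feature("f1", "negative", mass - PROTON_MASS, 2.0)
        comps = [
            CompoundRecord("far", "a", "", mass * (1 + 10e-6)),
            CompoundRecord("near", "b", "", mass * (1 - 2e-6)),
        ]
        anns = annotate([feat], comps)
        assert [a.compound_id for a in anns] == ["near", "far"]


def _single_linkage_oracle(peaks, mz_tol_ppm, rt_tol_min):
    """Union-find single-linkage clustering under both tolerances."""
    parent = list(range(len(peaks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            ppm = 1e6 * abs(peaks[i].mz - peaks[j].mz) / peaks[i].mz
            if ppm <= mz_tol_ppm and abs(peaks[i].rt - peaks[j].rt) <= rt_tol_min:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(len(peaks))})


class TestJoinAlign:
    def test_identical_peak_across_two_runs_joins(self):
        runs = [
            PeakList("R1", "sample", "positive",
                     [Peak(250.0, 5.0, 1e5)], "benign"),
            PeakList("R2", "sample", "positive",
                     [Peak(250.0, 5.0, 2e5)], "benign"),
        ]
        table = join_align(runs)
        assert table.n_features == 1
        assert np.count_nonzero(table.intensities) == 2

    def test_fifty_ppm_apart_stays_split(self):
        runs = [
            PeakList("R1", "sample", "positive", [Peak(100.0000, 5.0, 1e5)], "benign"),
            PeakList("R2", "sample", "positive", [Peak(100.0050, 5.0, 1e5)], "benign"),
        ]
        assert join_align(runs).n_features == 2

    def test_mixed_modes_rejected(self):
        runs = [
            PeakList("R1", "sample", "positive", [Peak(100.0, 5.0, 1e5)], "benign"),
            PeakList("R2", "sample", "negative", [Peak(100.0, 5.0, 1e5)], "benign"),
        ]
        with pytest.raises(ValidationError):
            join_align(runs)

    def test_single_run_alignment_is_identity(self):
        rng = np.random.default_rng(0)
        peaks = [
            Peak(float(m), float(t), float(v))
            for m, t, v in zip(
                rng.uniform(80, 999, 30), rng.uniform(1, 24, 30),
                rng.uniform(1e3, 1e6, 30),
            )
        ]
        pl = PeakList("R1", "sample", "positive", peaks, "benign")
        table = join_align([pl])
        assert table.n_features == 30
        np.testing.assert_allclose(
            np.sort(table.intensities.ravel()),
            np.sort([p.intensity for p in peaks]),
        )

    def test_jittered_ions_recovered_exactly(self):
        """5 runs x 20 true ions jittered within tolerance -> 20 features."""
        rng = np.random.default_rng(1)
        true_mz = np.sort(rng.uniform(100, 900, 20))
        true_rt = rng.uniform(1, 24, 20)
        runs = []
        all_peaks = []
        for r in range(5):
            peaks = []
            for m, t in zip(true_mz, true_rt):
                jm = m * (1 + rng.uniform(-3e-6, 3e-6))
                jt = t + rng.uniform(-0.2, 0.2)
                peaks.append(Peak(float(jm), float(jt), float(rng.uniform(1e4, 1e6))))
            runs.append(PeakList(f"R{r}", "sample", "positive", peaks, "benign"))
            all_peaks.extend(peaks)
        table = join_align(runs)
        assert table.n_features == 20
        assert table.n_features == _single_linkage_oracle(all_peaks, 10.0, 1.0)
        # every run contributed one peak per feature
        assert np.count_nonzero(table.intensities) == 100

    def test_tolerance_monotonicity(self):
        rng = np.random.default_rng(2)
        runs = []
        for r in range(4):
            peaks = [
                Peak(float(m), float(t), 1e5)
                for m, t in zip(rng.uniform(100, 200, 25), rng.uniform(1, 24, 25))
            ]
            runs.append(PeakList(f"R{r}", "sample", "positive", peaks, "benign"))
        counts = [
            join_align(runs, mz_tol_ppm=ppm, rt_tol_min=rt).n_features
            for ppm, rt in [(5, 0.5), (10, 1.0), (50, 2.0), (200, 5.0)]
        ]
        assert counts == sorted(counts, reverse=True)


class TestMergeModes:
    def test_counts_add(self, aligned_fixture, fixture_cohort):
        merged, _, _ = aligned_fixture
        peak_lists, _, _ = fixture_cohort
        pos = join_align(peak_lists["positive"])
        neg = join_align(peak_lists["negative"])
        assert merged.n_features == pos.n_features + neg.n_features

    def test_empty_negative_is_identity(self):
        runs = [PeakList("R1", "sample", "positive", [Peak(100.0, 5.0, 1e5)], "benign")]
        pos = join_align(runs)
        neg_runs = [PeakList("R1", "sample", "negative", [], "benign")]
        neg = join_align(neg_runs)
        merged = merge_modes(pos, neg)
        assert merged.n_features == pos.n_features
        np.testing.assert_allclose(merged.intensities, pos.intensities)

    def test_sample_mismatch_lists_run_ids(self):
        pos = join_align(
            [PeakList("R1", "sample", "positive", [Peak(100.0, 5.0, 1e5)], "benign")]
        )
        neg = join_align(
            [PeakList("R2", "sample", "negative", [Peak(100.0, 5.0, 1e5)], "benign")]
        )
        with pytest.raises(ValidationError, match="R2"):
            merge_modes(pos, neg)
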
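"""Correction matrices, natural-isotope correction and purity correction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isocalc import (
    FragmentIon,
    LabelingRecord,
    TracerSpec,
    areas_to_mdv,
    batch_correct,
    build_correction_matrix,
    correct_natural,
    correct_purity,
    parse_formula,
)

from conftest import random_small_ion


def ion(formula: str, n: int, name: str = "x") -> FragmentIon:
    return FragmentIon(name, parse_formula(formula), 1, n)


class TestBuildCorrectionMatrix:
    def test_pure_table_gives_identity(self, pure_table, tracer_13c):
        cm = build_correction_matrix(ion("C4H6O4", 3), tracer_13c, 0,
                                     table=pure_table)
        np.testing.assert_allclose(cm.matrix, np.eye(4), atol=0)

    def test_co2_matrix(self, table, tracer_13c):
        # frozen from the enumeration oracle with the default table:
        # col 0 = natural dist of CO2, col 1 = natural dist of O2
        cm = build_correction_matrix(ion("CO2", 1), tracer_13c, 0, table=table)
        np.testing.assert_allclose(
            cm.matrix, [[0.98436, 0.0], [0.011436, 0.99500625]], atol=1e-4
        )

    def test_element_subset_restricts_spread(self, table, tracer_13c):
        cm = build_correction_matrix(
            ion("CO2", 1), tracer_13c, 0, elements={"C"}, table=table
        )
        np.testing.assert_allclose(cm.matrix, [[0.9893, 0], [0.0107, 1.0]], atol=1e-12)

    def test_lower_band_structure(self, table, tracer_13c):
        cm = build_correction_matrix(ion("C5H8O4Si", 4), tracer_13c, 2, table=table)
        assert cm.matrix.shape == (7, 5)
        for j in range(5):
            assert np.all(cm.matrix[:j, j] == 0)
            assert cm.matrix[:, j].sum() <= 1 + 1e-12
        assert np.all(cm.matrix >= 0) and np.all(cm.matrix <= 1)

    def test_column_sums_approach_one_with_extra(self, table, tracer_13c):
        small = build_correction_matrix(ion("C20H40O10Si2", 5), tracer_13c, 0,
                                        table=table)
        big = build_correction_matrix(ion("C20H40O10Si2", 5), tracer_13c, 30,
                                      table=table)
        assert np.all(big.matrix.sum(axis=0) > small.matrix.sum(axis=0))
        np.testing.assert_allclose(big.matrix.sum(axis=0), 1.0, atol=1e-6)

    def test_column_shift_identity(self, table, tracer_13c):
        """Column j of CM(ion) is column 0 of CM(ion minus j tracer atoms)
        shifted down j rows."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            base = random_small_ion(rng)
            n = base.n_tracer_positions
            cm = build_correction_matrix(base, tracer_13c, 2, table=table)
            for j in range(n + 1):
                reduced = FragmentIon(
                    base.name,
                    base.formula.remove("C", j),
                    base.charge,
                    n - j,
                )
                cm_red = build_correction_matrix(reduced, tracer_13c, 2,
                                                 table=table)
                depth = cm.matrix.shape[0] - j
                np.testing.assert_allclose(
                    cm.matrix[j:, j], cm_red.matrix[:depth, 0], atol=1e-12
                )

    def test_bad_inputs(self, table, tracer_13c):
        with pytest.raises(ValueError):
            build_correction_matrix(ion("CO2", 1), tracer_13c, -1, table=table)
        with pytest.raises(ValueError, match="exceed"):
            build_correction_matrix(ion("CO2", 2), tracer_13c, 0, table=table)
        with pytest.raises(ValueError, match="not in"):
            build_correction_matrix(ion("CO2", 1), tracer_13c, 0,
                                    elements={"Si"}, table=table)


class TestAreasToMdv:
    def test_normalizes(self):
        np.testing.assert_allclose(
            areas_to_mdv([100, 50, 50]).values, [0.5, 0.25, 0.25]
        )

    def test_clips_negative_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            mdv = areas_to_mdv([80, -5, 20])
        np.testing.assert_allclose(mdv.values, [0.8, 0, 0.2])
        assert any("clipped" in r.message for r in caplog.records)

    def test_all_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="rec42"):
            areas_to_mdv([0, 0, 0], record_id="rec42")


class TestCorrectNatural:
    def test_unlabeled_round_trip(self, table, tracer_13c):
        cm = build_correction_matrix(ion("C17H40O7PSi3", 3), tracer_13c, 3,
                                     table=table)
        corrected, diag = correct_natural(cm.matrix[:, 0], cm)
        np.testing.assert_allclose(corrected.values, [1, 0, 0, 0], atol=1e-10)
        assert diag.ok

    def test_forward_invert_round_trip(self, table, tracer_13c):
        cm = build_correction_matrix(ion("C17H40O7PSi3", 3), tracer_13c, 3,
                                     table=table)
        v = np.array([0.5, 0.5, 0.0, 0.0])
        corrected, diag = correct_natural(cm.matrix @ v, cm)
        np.testing.assert_allclose(corrected.values, v, atol=1e-8)
        assert diag.residual < 1e-10

    @pytest.mark.parametrize("extra", [0, 3])
    def test_random_simplex_round_trips(self, table, tracer_13c, extra):
        rng = np.random.default_rng(11)
        for _ in range(20):
            target = random_small_ion(rng)
            cm = build_correction_matrix(target, tracer_13c, extra, table=table)
            v = rng.dirichlet(np.ones(cm.n_states))
            corrected, _ = correct_natural(cm.matrix @ v, cm)
            np.testing.assert_allclose(corrected.values, v, atol=1e-8)

    def test_nnls_round_trip(self, table, tracer_13c):
        cm = build_correction_matrix(ion("C6H12O6", 3), tracer_13c, 3, table=table)
        v = np.array([0.1, 0.2, 0.3, 0.4])
        corrected, _ = correct_natural(cm.matrix @ v, cm, nonnegative=True)
        np.testing.assert_allclose(corrected.values, v, atol=1e-8)

    def test_output_on_simplex(self, table, tracer_13c):
        rng = np.random.default_rng(3)
        cm = build_correction_matrix(ion("C10H20O5Si2", 4), tracer_13c, 3,
                                     table=table)
        for _ in range(10):
            raw = rng.dirichlet(np.ones(cm.n_channels))
            corrected, _ = correct_natural(raw, cm)
            assert np.all(corrected.values >= 0)
            assert corrected.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_misfit_is_flagged_not_dropped(self, table, tracer_13c):
        cm = build_correction_matrix(ion("C3H6O3", 3), tracer_13c, 0, table=table)
        # physically impossible raw vector: all signal in the top channel
        corrected, diag = correct_natural(np.array([0, 0, 0, 1.0]), cm,
                                          tolerance=1e-3)
        assert not diag.ok or np.all(diag.raw_solution >= -1e-3)
        assert corrected.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_dimension_mismatch(self, table, tracer_13c):
        cm = build_correction_matrix(ion("CO2", 1), tracer_13c, 0, table=table)
        with pytest.raises(ValueError, match="length"):
            correct_natural(np.array([1.0, 0, 0]), cm)


class TestCorrectPurity:
    def test_alpha_one_is_identity(self):
        t = TracerSpec("C", purity=1.0)
        v = np.array([0.3, 0.7])
        np.testing.assert_array_equal(correct_purity(v, t).values, v)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        st.floats(0.5, 1.0),
    )
    def test_mixture_round_trip(self, lab, nat, alpha):
        k = min(len(lab), len(nat))
        labeled = np.array(lab[:k]) / np.sum(lab[:k])
        natural = np.array(nat[:k]) / np.sum(nat[:k])
        t = TracerSpec("C", purity=alpha)
        measured = alpha * labeled + (1 - alpha) * natural
        out = correct_purity(measured, t, natural)
        np.testing.assert_allclose(out.values, labeled, atol=1e-9)

    def test_default_natural_is_unlabeled(self):
        t = TracerSpec("C", purity=0.9)
        labeled = np.array([0.2, 0.8])
        measured = 0.9 * labeled + 0.1 * np.array([1.0, 0.0])
        np.testing.assert_allclose(correct_purity(measured, t).values, labeled,
                                   atol=1e-12)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            TracerSpec("C", purity=0.0)
        with pytest.raises(ValueError):
            TracerSpec("C", purity=1.0001)

    def test_length_mismatch(self):
        t = TracerSpec("C", purity=0.9)
        with pytest.raises(ValueError, match="length"):
            correct_purity(np.array([0.5, 0.5]), t, np.array([1.0, 0, 0]))


class TestBatchCorrect:
    def _records(self, targets, tracer, table, per_target=1):
        rng = np.random.default_rng(5)
        recs = []
        for t in targets:
            cm = build_correction_matrix(t, tracer, 3, table=table)
            for r in range(per_target):
                v = rng.dirichlet(np.ones(cm.n_states))
                recs.append(
                    LabelingRecord(f"s{r}", t.name, 1e5 * (cm.matrix @ v))
                )
        return recs

    def test_counts_and_round_trip(self, table, tracer_13c):
        targets = [ion("C6H12O6", 3, "a"), ion("C5H8O4Si", 4, "b")]
        recs = self._records(targets, tracer_13c, table, per_target=3)
        results, log = batch_correct(recs, {t.name: t for t in targets},
                                     tracer_13c, 3, table=table)
        assert log.processed == 6
        assert not log.errors
        assert len(results) == 6

    def test_empty_input(self, tracer_13c):
        results, log = batch_correct([], {}, tracer_13c)
        assert results == [] and log.processed == 0

    def test_unknown_metabolite_isolated(self, table, tracer_13c):
        targets = [ion("C6H12O6", 3, "known")]
        recs = self._records(targets, tracer_13c, table, per_target=9)
        recs.append(LabelingRecord("s0", "mystery", np.ones(7)))
        results, log = batch_correct(recs, {t.name: t for t in targets},
                                     tracer_13c, 3, table=table)
        assert log.processed == 9
        assert len(log.errors) == 1 and "mystery" in log.errors[0][1]

    def test_purity_applied_when_below_one(self, table):
        t_pure = TracerSpec.from_string("13C")
        t_impure = t_pure.with_purity(0.9)
        targets = [ion("C3H6O3", 3, "m")]
        cm = build_correction_matrix(targets[0], t_pure, 3, table=table)
        labeled = np.array([0.1, 0.2, 0.3, 0.4])
        natural = np.zeros(4)
        natural[0] = 1.0
        measured = 0.9 * labeled + 0.1 * natural
        rec = LabelingRecord("s", "m", 1e6 * (cm.matrix @ measured))
        results, _ = batch_correct([rec], {"m": targets[0]}, t_impure, 3,
                                   table=table)
        np.testing.assert_allclose(results[0][1].values, labeled, atol=1e-6)
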
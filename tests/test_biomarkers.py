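"""Compound-specific corrections, 13C incorporation and pool aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizotrace import biomarkers as bm


class TestCompoundTable:
    def test_bundled_table_loads(self):
        table = bm.load_compound_table()
        assert set(table["biomarker_class"]) == {"PLFA", "AS", "AA"}
        assert set(table[table["biomarker_class"] == "AS"].index) == set(bm.AS_COMPOUNDS)
        assert set(table[table["biomarker_class"] == "AA"].index) == set(bm.AA_COMPOUNDS)
        assert ((table["carbon_fraction"] > 0) & (table["carbon_fraction"] < 1)).all()

    def test_carbon_mass_fraction_palmitic(self):
        # C16H32O2: MW = 16*12.011 + 32*1.008 + 2*15.999 = 256.43
        expected = 16 * 12.011 / (16 * 12.011 + 32 * 1.008 + 2 * 15.999)
        assert bm.carbon_mass_fraction("C16H32O2") == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.7494, abs=1e-4)

    def test_carbon_mass_fraction_glucosamine(self):
        # C6H13NO5: MW = 179.17
        assert bm.carbon_mass_fraction("C6H13NO5") == pytest.approx(6 * 12.011 / 179.171, abs=1e-4)

    def test_bad_formula(self):
        for bad in ("X5", "H2O", "C6H13$"):
            with pytest.raises(ValueError):
                bm.carbon_mass_fraction(bad)


class TestDerivatizationDilution:
    def test_mixing_equation_example(self):
        got = bm.correct_derivatization_dilution(-30.0, 16, 1, -40.0)
        assert got == pytest.approx((17 * -30.0 - 1 * -40.0) / 16, abs=1e-12)
        assert got == pytest.approx(-29.375)

    def test_identity_no_added_carbon(self):
        assert bm.correct_derivatization_dilution(-30.0, 16, 0, -40.0) == -30.0

    def test_no_contrast(self):
        assert bm.correct_derivatization_dilution(-30.0, 16, 3, -30.0) == pytest.approx(-30.0)

    def test_zero_analyte_carbon(self):
        with pytest.raises(ValueError):
            bm.correct_derivatization_dilution(-30.0, 0, 1, -40.0)

    @given(
        st.integers(min_value=1, max_value=30),
        st.integers(min_value=0, max_value=10),
        st.floats(min_value=-100.0, max_value=5000.0),
        st.floats(min_value=-60.0, max_value=-20.0),
    )
    @settings(max_examples=300, derandomize=True)
    def test_forward_then_correct_round_trip(self, n_analyte, n_added, delta, reagent):
        diluted = bm.dilute_delta(delta, n_analyte, n_added, reagent)
        recovered = bm.correct_derivatization_dilution(diluted, n_analyte, n_added, reagent)
        assert recovered == pytest.approx(delta, abs=1e-9)

    @given(
        st.sampled_from(sorted(bm.load_compound_table().index)),
        st.floats(min_value=-60.0, max_value=0.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_delta_vs_atom_fraction_scale_agreement(self, compound, delta_analyte):
        # for natural-abundance analytes/reagents and the panel's real carbon
        # counts, the linear-mixing approximation agrees with the exact
        # atom-fraction balance to ~0.01 permil (worst case 0.011 permil for
        # the smallest analyte at a 40 permil analyte-reagent contrast)
        table = bm.load_compound_table()
        n_analyte = int(table.loc[compound, "n_carbon"])
        n_added = int(table.loc[compound, "n_carbon_added"])
        diluted = bm.dilute_delta(delta_analyte, n_analyte, n_added, -40.0, scale="atom_fraction")
        a = bm.correct_derivatization_dilution(diluted, n_analyte, n_added, -40.0, scale="delta")
        b = bm.correct_derivatization_dilution(diluted, n_analyte, n_added, -40.0, scale="atom_fraction")
        assert b == pytest.approx(delta_analyte, abs=1e-9)
        assert a == pytest.approx(b, abs=0.02)


class TestInstrumentCorrection:
    def _cal(self, offset=0.0, drift=0.0, amount_slope=0.0, n=12):
        runs = np.arange(n)
        # amounts deliberately shuffled against run order to keep the design
        # well conditioned (drift and amount terms must be separable)
        amounts = np.logspace(0.5, 2.5, n)
        amounts = amounts[(runs * 5) % n]
        true = np.tile([-30.0, -25.0, -20.0], n)[:n]
        measured = true + offset + drift * runs + amount_slope * np.log(amounts)
        return pd.DataFrame(
            {"true_delta": true, "measured_delta": measured, "amount": amounts, "run_index": runs}
        )

    def test_exact_standards_give_zero_model(self):
        model = bm.fit_instrument_correction(self._cal())
        assert model.offset == pytest.approx(0.0, abs=1e-10)
        assert model.drift_slope == pytest.approx(0.0, abs=1e-10)
        assert model.amount_slope == pytest.approx(0.0, abs=1e-10)
        assert bm.CorrectionModel().is_identity

    def test_constant_bias_recovered(self):
        model = bm.fit_instrument_correction(self._cal(offset=0.5))
        assert model.offset == pytest.approx(0.5, abs=1e-9)
        assert model.drift_slope == pytest.approx(0.0, abs=1e-9)

    def test_drift_recovered(self):
        model = bm.fit_instrument_correction(self._cal(offset=0.2, drift=0.02))
        assert model.drift_slope == pytest.approx(0.02, abs=1e-9)

    def test_amount_dependence_recovered(self):
        model = bm.fit_instrument_correction(self._cal(amount_slope=-0.15))
        assert model.amount_slope == pytest.approx(-0.15, abs=1e-9)

    def test_rank_deficiency_names_term(self):
        cal = self._cal()
        cal["amount"] = 10.0
        with pytest.raises(ValueError, match="amount"):
            bm.fit_instrument_correction(cal)
        cal2 = self._cal()
        cal2["run_index"] = 3
        with pytest.raises(ValueError, match="run_index"):
            bm.fit_instrument_correction(cal2)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            bm.fit_instrument_correction(self._cal().head(1))

    def test_apply_identity(self):
        assert bm.apply_correction(bm.CorrectionModel(), -29.0, amount=10, run_index=3) == -29.0

    def test_apply_offset_only(self):
        assert bm.apply_correction(bm.CorrectionModel(offset=0.5), -29.0) == pytest.approx(-29.5)

    def test_composition_golden(self):
        # fixed order: measured - offset - drift*run - slope*log(amount)
        model = bm.CorrectionModel(offset=0.3, drift_slope=0.01, amount_slope=-0.15)
        got = bm.apply_correction(model, -28.0, amount=50.0, run_index=7)
        by_hand = -28.0
        by_hand -= 0.3
        by_hand -= 0.01 * 7
        by_hand -= -0.15 * np.log(50.0)
        assert got == pytest.approx(by_hand, abs=1e-12)

    def test_missing_covariate(self):
        model = bm.CorrectionModel(drift_slope=0.01)
        with pytest.raises(ValueError, match="run_index"):
            bm.apply_correction(model, -28.0)


class TestIncorporation:
    def test_labeled_equals_background(self):
        assert bm.biomarker_13c_incorporation(10.0, 0.5, -27.0, -27.0) == 0.0

    def test_zero_concentration(self):
        assert bm.biomarker_13c_incorporation(0.0, 0.5, 100.0, -27.0) == 0.0

    def test_product_oracle(self):
        # APE 0.5 atom% on 10 ug C/g gives 0.05 ug 13C/g
        from rhizotrace.isotope import atom_percent_to_delta, delta_to_atom_percent

        bg = -27.0
        labeled = atom_percent_to_delta(delta_to_atom_percent(bg) + 0.5)
        got = bm.biomarker_13c_incorporation(20.0, 0.5, labeled, bg)
        assert got == pytest.approx(0.05, abs=1e-9)


def _records(rows):
    df = pd.DataFrame(rows)
    df["sample_id"] = "S1"
    return df


class TestPoolSummary:
    def test_single_compound(self):
        rec = _records(
            [dict(compound="GlcN", biomarker_class="AS", concentration_ug_per_g=10.0,
                  c_content_ug_per_g=4.0, incorporation_ug_13c_per_g=0.04)]
        )
        ps = bm.pool_summary(rec)
        assert ps.weighted_ape == pytest.approx(1.0)
        assert ps.n_compounds == 1

    def test_equal_carbon_mean(self):
        rec = _records(
            [
                dict(compound="GlcN", biomarker_class="AS", concentration_ug_per_g=1.0,
                     c_content_ug_per_g=10.0, incorporation_ug_13c_per_g=0.1),
                dict(compound="MurN", biomarker_class="AS", concentration_ug_per_g=1.0,
                     c_content_ug_per_g=10.0, incorporation_ug_13c_per_g=0.3),
            ]
        )
        assert bm.pool_summary(rec).weighted_ape == pytest.approx(2.0)

    def test_weighted_mean_oracle(self):
        # C 10 at APE 2 and C 30 at APE 0.4: (0.2 + 0.12) / 40 * 100 = 0.8
        rec = _records(
            [
                dict(compound="GlcN", biomarker_class="AS", concentration_ug_per_g=1.0,
                     c_content_ug_per_g=10.0, incorporation_ug_13c_per_g=0.2),
                dict(compound="MurN", biomarker_class="AS", concentration_ug_per_g=1.0,
                     c_content_ug_per_g=30.0, incorporation_ug_13c_per_g=0.12),
            ]
        )
        assert bm.pool_summary(rec).weighted_ape == pytest.approx(0.8)

    @given(st.lists(st.tuples(st.floats(0.1, 100.0), st.floats(0.0, 5.0)), min_size=1, max_size=8))
    @settings(max_examples=200, derandomize=True)
    def test_convexity(self, comps):
        compounds = ["GlcN", "GalN", "MurN", "ManN"] * 2
        rec = _records(
            [
                dict(compound=compounds[i], biomarker_class="AS", concentration_ug_per_g=1.0,
                     c_content_ug_per_g=c, incorporation_ug_13c_per_g=c * ape / 100.0)
                for i, (c, ape) in enumerate(comps)
            ]
        )
        ps = bm.pool_summary(rec)
        apes = [ape for _, ape in comps]
        assert min(apes) - 1e-9 <= ps.weighted_ape <= max(apes) + 1e-9

    def test_additive_and_permutation_invariant(self):
        rows = [
            dict(compound=c, biomarker_class="AS", concentration_ug_per_g=i + 1.0,
                 c_content_ug_per_g=3.0 * (i + 1), incorporation_ug_13c_per_g=0.01 * (i + 1))
            for i, c in enumerate(["GlcN", "GalN", "MurN"])
        ]
        a = bm.pool_summary(_records(rows))
        b = bm.pool_summary(_records(rows[::-1]))
        assert a.total_c == pytest.approx(b.total_c, rel=1e-12)
        assert a.total_13c_excess == pytest.approx(b.total_13c_excess, rel=1e-12)
        ab = bm.pool_summary(_records(rows + rows))
        assert ab.total_c == pytest.approx(2 * a.total_c)

    def test_empty_pool_is_absent_not_zero(self):
        with pytest.raises(ValueError, match="empty pool"):
            bm.pool_summary(_records([]).reindex(columns=["compound", "biomarker_class"]))

    def test_compound_outside_class_rejected(self):
        rec = _records(
            [dict(compound="C16:0", biomarker_class="AS", concentration_ug_per_g=1.0,
                  c_content_ug_per_g=1.0, incorporation_ug_13c_per_g=0.0)]
        )
        with pytest.raises(ValueError, match="C16:0"):
            bm.pool_summary(rec)


class TestProcessBiomarkers:
    def _table(self, include_background=True):
        rows = []
        for labeled in ([True, False] if include_background else [True]):
            for comp, cls in (("GlcN", "AS"), ("C16:0", "PLFA")):
                rows.append(
                    dict(plot_id="P1" if labeled else "BG1", species="lucerne", n_rate=0,
                         depth_top_cm=0, depth_bottom_cm=25, matrix="rhizosphere_soil",
                         compound=comp, biomarker_class=cls, concentration_ug_per_g=10.0,
                         d13c_measured=(-20.0 if labeled else -25.0), run_index=0,
                         peak_amount=5.0, is_labeled=labeled)
                )
        return pd.DataFrame(rows)

    REAGENT = {"AS": -35.0, "PLFA": -40.0, "AA": -38.0}

    def test_end_to_end_small(self):
        corrected, pools = bm.process_biomarkers(self._table(), self.REAGENT)
        assert len(corrected) == 2 and len(pools) == 2
        assert (corrected["incorporation_ug_13c_per_g"] > 0).all()
        assert set(pools["biomarker_class"]) == {"AS", "PLFA"}

    def test_missing_background_lists_compound_and_depth(self):
        df = self._table()
        df = df[~((df["compound"] == "GlcN") & ~df["is_labeled"])]
        with pytest.raises(ValueError, match="GlcN"):
            bm.process_biomarkers(df, self.REAGENT)

    def test_missing_reagent_class(self):
        with pytest.raises(ValueError, match="PLFA"):
            bm.process_biomarkers(self._table(), {"AS": -35.0})

    def test_unknown_compound(self):
        df = self._table()
        df.loc[0, "compound"] = "C99:9"
        with pytest.raises(ValueError, match="C99:9"):
            bm.process_biomarkers(df, self.REAGENT)

    def test_class_mismatch_with_table(self):
        df = self._table()
        df.loc[df["compound"] == "GlcN", "biomarker_class"] = "PLFA"
        with pytest.raises(ValueError, match="GlcN"):
            bm.process_biomarkers(df, self.REAGENT)
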
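"""Damage metrics: normalization, indices, hydration, propagation."""

import numpy as np
import pandas as pd
import pytest

from napxps import synth
from napxps.damage import (
    base_damage_index,
    damage_report_table,
    load_rsf,
    normalize_series_table,
    strand_break_index,
    water_per_nucleotide_table,
)
from napxps.fitting import RegionFitModel
from napxps.peakmodel import default_region_models


def _table(rows):
    return pd.DataFrame(
        rows, columns=["region", "timepoint_s", "component", "area",
                       "sigma", "is_gas_phase"]
    )


def _simple_table(c286=(10.0, 5.0), p2p=(4.0, 4.0), sigma=0.0):
    rows = []
    for i, t in enumerate((0.0, 100.0)):
        rows += [
            ("C1s", t, "C1s_285", 8.0, sigma, False),
            ("C1s", t, "C1s_286", c286[i], sigma, False),
            ("N1s", t, "N1s_399", 6.0, sigma, False),
            ("N1s", t, "N1s_401", 4.0, sigma, False),
            ("P2p", t, "P2p_32", p2p[i] * 2 / 3, sigma, False),
            ("P2p", t, "P2p_12", p2p[i] / 3, sigma, False),
        ]
    return _table(rows)


class TestNormalization:
    def test_constant_areas_give_constant_percent_series(self):
        tab = _simple_table(c286=(10.0, 10.0))
        series = normalize_series_table(tab)
        c = series["C1s"].component("C1s_286")
        assert c["percent_of_initial"].nunique() == 1

    def test_initial_percents_sum_to_100_over_non_gas(self):
        tab = _simple_table()
        series = normalize_series_table(tab)
        for reg, ser in series.items():
            first = ser.table[ser.table["timepoint_s"] == 0.0]
            tot = first.loc[~first["is_gas_phase"], "percent_of_initial"].sum()
            assert tot == pytest.approx(100.0, abs=1e-9)

    def test_scale_invariance(self):
        tab = _simple_table(sigma=0.1)
        scaled = tab.copy()
        scaled["area"] *= 7.5
        scaled["sigma"] *= 7.5
        a = normalize_series_table(tab)["C1s"].table
        b = normalize_series_table(scaled)["C1s"].table
        pd.testing.assert_frame_equal(a, b)

    def test_doubling_one_timepoint_including_reference_changes_nothing(self):
        tab = _simple_table()
        boosted = tab.copy()
        sel = boosted["timepoint_s"] == 100.0
        boosted.loc[sel, "area"] *= 2.0
        a = normalize_series_table(tab)["C1s"].table["normalized_area"]
        b = normalize_series_table(boosted)["C1s"].table["normalized_area"]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_missing_reference_timepoint_dropped_with_warning(self, caplog):
        tab = _simple_table()
        tab = tab[~((tab["region"] == "P2p") & (tab["timepoint_s"] == 100.0))]
        with caplog.at_level("WARNING"):
            series = normalize_series_table(tab)
        assert "dropping" in caplog.text
        assert list(series["C1s"].timepoints) == [0.0]

    def test_gas_phase_excluded_from_totals_but_still_normalized(self):
        rows = [
            ("N1s", 0.0, "N1s_399", 6.0, 0.0, False),
            ("N1s", 0.0, "N1s_405", 3.0, 0.0, True),
            ("P2p", 0.0, "P2p_32", 2.0, 0.0, False),
        ]
        ser = normalize_series_table(_table(rows))["N1s"].table
        cond = ser[ser["component"] == "N1s_399"].iloc[0]
        gas = ser[ser["component"] == "N1s_405"].iloc[0]
        assert cond["percent_of_initial"] == pytest.approx(100.0)
        assert gas["normalized_area"] == pytest.approx(1.5)


class TestIndices:
    def test_identical_endpoints_give_zero_indices(self):
        series = normalize_series_table(_simple_table(c286=(10.0, 10.0)))
        assert strand_break_index(series["C1s"])[0] == pytest.approx(0.0)
        assert base_damage_index(series["N1s"])[0] == pytest.approx(0.0)

    def test_halved_component_gives_one_half(self):
        series = normalize_series_table(_simple_table(c286=(10.0, 5.0)))
        val, _ = strand_break_index(series["C1s"])
        assert val == pytest.approx(0.5)

    def test_reference_drift_cancels_in_the_index(self):
        # component constant but P2p halves: normalized area doubles
        series = normalize_series_table(
            _simple_table(c286=(10.0, 10.0), p2p=(4.0, 2.0)))
        val, _ = strand_break_index(series["C1s"])
        assert val == pytest.approx(-1.0)  # apparent growth, by construction

    def test_single_component_region_reduces_to_component_decrease(self):
        rows = []
        for t, a in ((0.0, 6.0), (50.0, 4.5)):
            rows += [("N1s", t, "N1s_399", a, 0.0, False),
                     ("P2p", t, "P2p_32", 3.0, 0.0, False)]
        series = normalize_series_table(_table(rows))
        val, _ = base_damage_index(series["N1s"])
        assert val == pytest.approx(0.25)

    def test_zero_start_area_is_undefined(self):
        series = normalize_series_table(_simple_table(c286=(0.0, 0.0)))
        with pytest.raises(ValueError, match="undefined"):
            strand_break_index(series["C1s"])

    def test_sigma_propagation_matches_hand_formula(self):
        tab = _simple_table(c286=(10.0, 5.0), sigma=0.3)
        series = normalize_series_table(tab)
        val, sig = strand_break_index(series["C1s"])
        c = series["C1s"].component("C1s_286")
        r0, s0 = c.iloc[0][["normalized_area", "sigma_norm"]]
        r1, s1 = c.iloc[1][["normalized_area", "sigma_norm"]]
        expected = np.sqrt((s1 / r0) ** 2 + (r1 * s0 / r0**2) ** 2)
        assert sig == pytest.approx(expected, rel=1e-12)


class TestWaterPerNucleotide:
    def _tab(self, water_area, p2p=3.0):
        rows = [
            ("O1s", 0.0, "O1s_532", 5.0, 0.0, False),
            ("O1s", 0.0, "O1s_535", water_area, 0.0, True),
            ("P2p", 0.0, "P2p_32", p2p * 2 / 3, 0.0, False),
            ("P2p", 0.0, "P2p_12", p2p / 3, 0.0, False),
        ]
        return _table(rows)

    def test_zero_water_area_gives_zero(self):
        val, sig = water_per_nucleotide_table(self._tab(0.0))
        assert val == 0.0

    def test_corrected_ratio_of_five_gives_five(self):
        rsf = load_rsf()
        area = 5.0 * rsf["O1s"] / rsf["P2p"] * 3.0
        val, _ = water_per_nucleotide_table(self._tab(area))
        assert val == pytest.approx(5.0, rel=1e-12)

    def test_missing_rsf_entry_is_configuration_error(self):
        with pytest.raises(KeyError, match="P2p"):
            water_per_nucleotide_table(self._tab(1.0), rsf={"O1s": 2.93})

    def test_programmed_quarter_water_recovered_from_fits(self, region_models):
        sc = synth.preset_scenarios(snr=100.0)["vacuum"]
        sc.timepoints = (0.0, 100.0)
        series, _ = synth.generate_series(sc, seed=77)
        rows = []
        for region in ("O1s", "P2p"):
            fr = RegionFitModel(series.get(region, 0.0),
                                region_models[region]).fit()
            for c in fr.model.components:
                a, s = fr.component_areas[c.label]
                rows.append((region, 0.0, c.label, a, s, c.is_gas_phase))
        val, sig = water_per_nucleotide_table(_table(rows))
        assert val == pytest.approx(0.25, rel=0.10)


class TestMonotonicity:
    def test_strand_break_index_increases_with_decay_rate(self, region_models):
        # five-point rate grid, fixed seed, endpoint-only series
        vals = []
        for i, kt in enumerate((0.05, 0.15, 0.3, 0.6, 1.0)):
            sc = synth.DamageScenario(
                condition="N2",
                models={"C1s": region_models["C1s"],
                        "P2p": region_models["P2p"]},
                initial_areas={"C1s_285": 0.9, "C1s_286": 1.1,
                               "C1s_288": 0.55, "C1s_289": 0.3,
                               "P2p_32": 2 / 3, "P2p_12": 1 / 3},
                rates={"C1s_286": kt / 7200.0},
                timepoints=(0.0, 7200.0),
                snr=200.0,
                windows={"C1s": (280.0, 294.0), "P2p": (127.0, 140.0)},
            )
            series, _ = synth.generate_series(sc, seed=500 + i)
            rows = []
            for region in ("C1s", "P2p"):
                prev = None
                for s in series.by_region(region):
                    fr = RegionFitModel(s, region_models[region]).fit(
                        start_from=prev)
                    prev = fr
                    for c in fr.model.components:
                        a, sg = fr.component_areas[c.label]
                        rows.append((region, s.timepoint, c.label, a, sg,
                                     c.is_gas_phase))
            ser = normalize_series_table(_table(rows))
            vals.append(strand_break_index(ser["C1s"])[0])
        assert np.all(np.diff(vals) > 0)


class TestReportAssembly:
    def test_report_contains_all_pieces(self):
        sc = synth.preset_scenarios(snr=None)["vacuum"]
        sc.timepoints = (0.0, 7200.0)
        series, _ = synth.generate_series(sc, seed=0)
        models = default_region_models()
        rows = []
        for region in ("C1s", "N1s", "O1s", "P2p"):
            for s in series.by_region(region):
                fr = RegionFitModel(s, models[region],
                                    weighting="none").fit()
                for c in fr.model.components:
                    a, sg = fr.component_areas[c.label]
                    rows.append((region, s.timepoint, c.label, a, sg,
                                 c.is_gas_phase))
        rep = damage_report_table(_table(rows))
        assert rep.strand_break_index > 0
        assert rep.base_damage_index > 0
        assert rep.water_per_nucleotide == pytest.approx(0.25, rel=0.05)
        assert rep.strand_break_index > rep.base_damage_index
        d = rep.to_dict()
        assert set(d) >= {"strand_break_index", "base_damage_index",
                          "water_per_nucleotide", "end_start_ratios"}
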
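"""Spore geometry, mass-to-molarity, calibration, peak integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sporeglass import (
    AnalyteDef,
    SporeGeometry,
    composition_proportions,
    cytoplasmic_volume,
    fit_calibration,
    integrate_peaks,
    mass_to_molarity,
    quantify_sample,
)
from sporeglass.spectra import SpectrumContentError
from sporeglass import simulate as sim


class TestGeometry:
    def test_neosartorya_sphere_volume(self):
        # wall-excluded radius 2.0 um gives ~33.5 fl (reported 34 +/- 4)
        v = cytoplasmic_volume(SporeGeometry("sphere", 2.0))
        assert v == pytest.approx(33.5, abs=0.1)
        assert abs(v - 34.0) < 4.0

    def test_talaromyces_prolate_volume(self):
        # a=2.6, b=2.3 um gives ~57.6 fl (reported 55 +/- 8)
        v = cytoplasmic_volume(SporeGeometry("prolate_spheroid", 2.6, 2.3))
        assert v == pytest.approx(57.6, abs=0.1)
        assert abs(v - 55.0) < 8.0

    def test_sphere_equals_prolate_with_equal_axes(self):
        assert cytoplasmic_volume(SporeGeometry("sphere", 1.7)) == pytest.approx(
            cytoplasmic_volume(SporeGeometry("prolate_spheroid", 1.7, 1.7))
        )

    @given(
        a=st.floats(0.5, 5.0), b=st.floats(0.5, 5.0), da=st.floats(0.01, 1.0)
    )
    @settings(max_examples=30, deadline=None)
    def test_volume_strictly_increasing_in_each_axis(self, a, b, da):
        v0 = cytoplasmic_volume(SporeGeometry("prolate_spheroid", a, b))
        assert cytoplasmic_volume(SporeGeometry("prolate_spheroid", a + da, b)) > v0
        assert cytoplasmic_volume(SporeGeometry("prolate_spheroid", a, b + da)) > v0

    def test_nonpositive_axis_rejected(self):
        with pytest.raises(ValueError):
            SporeGeometry("sphere", -1.0)
        with pytest.raises(ValueError):
            SporeGeometry("prolate_spheroid", 2.0, 0.0)


class TestMassToMolarity:
    def test_talaromyces_mannitol(self):
        # 2.7 pg in the 55 fl prolate volume: reported 269 +/- 27 mM
        v = cytoplasmic_volume(SporeGeometry("prolate_spheroid", 2.6, 2.3))
        assert abs(mass_to_molarity(2.7, 182.17, v) - 269.0) < 27.0

    def test_neosartorya_trisaccharide(self):
        # 2.7 pg of the DP3 sugar in the 34 fl sphere: reported 156 +/- 11 mM
        v = cytoplasmic_volume(SporeGeometry("sphere", 2.0))
        assert abs(mass_to_molarity(2.7, 504.44, v) - 156.0) < 11.0

    def test_zero_mass_gives_zero(self):
        assert mass_to_molarity(0.0, 342.30, 34.0) == 0.0

    def test_zero_volume_rejected(self):
        with pytest.raises(SpectrumContentError):
            mass_to_molarity(1.0, 342.30, 0.0)

    @given(
        c=st.floats(1e-3, 1e3), mw=st.floats(50.0, 1000.0), v=st.floats(1.0, 100.0)
    )
    @settings(max_examples=50, deadline=None)
    def test_exact_round_trip(self, c, mw, v):
        # concentration -> pg/spore -> concentration is the identity
        pg = c * v * mw * 1e-6
        assert mass_to_molarity(pg, mw, v) == pytest.approx(c, rel=1e-12)


class TestCalibration:
    def test_exact_two_point_line(self):
        curve = fit_calibration([(0.1, 10.0), (0.5, 50.0)])
        assert curve.slope == pytest.approx(100.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)

    def test_recovers_simulated_response_factor(self):
        stds = []
        for i, conc in enumerate((0.005, 0.01, 0.02, 0.05)):
            p = sim.ChromSimParams(
                components=[sim.ChromComponent("tre", 7.9, 0.12, conc, 5000.0)],
                noise_sd=0.002,
            )
            chrom = sim.generate_chromatogram(p, 50 + i)
            area = integrate_peaks(
                chrom, [AnalyteDef("tre", 342.30, (7.3, 8.5))]
            )["tre"]
            stds.append((conc, area))
        curve = fit_calibration(stds, analyte="tre")
        assert curve.slope == pytest.approx(5000.0, rel=0.02)

    def test_duplicate_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(0.1, 10.0), (0.1, 10.5)])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(-0.1, 10.0), (0.5, 50.0)])


class TestIntegratePeaks:
    def test_single_gaussian_area(self):
        p = sim.ChromSimParams(
            components=[sim.ChromComponent("x", 10.0, 0.2, 2.0, 4.0)],
            baseline_offset=1.0, baseline_drift=0.05, noise_sd=0.0,
        )
        chrom = sim.generate_chromatogram(p, 0)
        area = integrate_peaks(chrom, [AnalyteDef("x", 100.0, (8.5, 11.5))])["x"]
        assert area == pytest.approx(8.0, rel=0.005)

    def test_flat_window_is_zero(self):
        p = sim.ChromSimParams(baseline_offset=2.0, baseline_drift=0.3, noise_sd=0.0)
        chrom = sim.generate_chromatogram(p, 0)
        area = integrate_peaks(chrom, [AnalyteDef("none", 100.0, (5.0, 8.0))])["none"]
        assert area == pytest.approx(0.0, abs=1e-9)

    def test_against_dense_grid_oracle(self):
        comps = [
            sim.ChromComponent("a", 6.0, 0.15, 1.0, 10.0),
            sim.ChromComponent("b", 14.0, 0.25, 2.0, 10.0),
        ]
        analytes = [
            AnalyteDef("a", 100.0, (5.0, 7.0)),
            AnalyteDef("b", 100.0, (12.5, 15.5)),
        ]
        coarse = sim.generate_chromatogram(
            sim.ChromSimParams(components=comps, noise_sd=0.0), 0
        )
        dense = sim.generate_chromatogram(
            sim.ChromSimParams(
                components=comps, noise_sd=0.0,
                time_grid=np.arange(0.0, 20.0, 0.0005),
            ),
            0,
        )
        got = integrate_peaks(coarse, analytes)
        # oracle: rectangle sum above the same endpoint baseline at 10x density
        for a in analytes:
            lo, hi = a.retention_window
            m = (dense.axis >= lo) & (dense.axis <= hi)
            x, y = dense.axis[m], dense.intensity[m]
            base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
            oracle = float(np.sum(y - base) * (x[1] - x[0]))
            assert got[a.name] == pytest.approx(oracle, rel=0.005)

    def test_overlapping_windows_rejected(self):
        chrom = sim.generate_chromatogram(sim.ChromSimParams(noise_sd=0.0), 0)
        analytes = [
            AnalyteDef("a", 100.0, (5.0, 8.0)),
            AnalyteDef("b", 100.0, (7.0, 9.0)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            integrate_peaks(chrom, analytes)

    def test_window_outside_axis_rejected(self):
        chrom = sim.generate_chromatogram(sim.ChromSimParams(noise_sd=0.0), 0)
        with pytest.raises(SpectrumContentError):
            integrate_peaks(chrom, [AnalyteDef("a", 100.0, (19.0, 25.0))])


class TestQuantifySample:
    GEOMETRY = SporeGeometry("sphere", 2.0)
    ANALYTES = [
        AnalyteDef("trehalose", 342.30, (7.3, 8.5)),
        AnalyteDef("mannitol", 182.17, (13.0, 14.6)),
    ]

    def _curves(self, noise_sd=0.001):
        curves = {}
        rts = {"trehalose": 7.9, "mannitol": 13.8}
        for name, rt in rts.items():
            stds = []
            for i, conc in enumerate((0.005, 0.01, 0.02, 0.05)):
                p = sim.ChromSimParams(
                    components=[sim.ChromComponent(name, rt, 0.12, conc, 5000.0)],
                    noise_sd=noise_sd,
                )
                area = integrate_peaks(
                    sim.generate_chromatogram(p, 200 + i), self.ANALYTES
                )[name]
                stds.append((conc, area))
            curves[name] = fit_calibration(stds, analyte=name)
        return curves

    def test_end_to_end_recovers_known_amounts(self):
        # 10^7 spores in 1 ml; 0.028 mg/ml mannitol = 2.8 pg/spore
        truth = {"trehalose": 0.028, "mannitol": 0.028}
        p = sim.ChromSimParams(
            components=[
                sim.ChromComponent("trehalose", 7.9, 0.12, truth["trehalose"], 5000.0),
                sim.ChromComponent("mannitol", 13.8, 0.15, truth["mannitol"], 5000.0),
            ],
            baseline_offset=0.2, noise_sd=0.001,
        )
        chrom = sim.generate_chromatogram(p, 9)
        out = quantify_sample(
            chrom, self._curves(), self.ANALYTES, 1e7, 1.0, self.GEOMETRY
        )
        for q in out:
            expected_pg = truth[q.analyte] * 1.0 * 1e9 / 1e7
            assert q.pg_per_spore == pytest.approx(expected_pg, rel=0.03)
            assert not q.below_loq

    def test_zero_amount_flagged_below_loq(self):
        p = sim.ChromSimParams(
            components=[
                sim.ChromComponent("trehalose", 7.9, 0.12, 0.02, 5000.0),
            ],
            noise_sd=0.0,
        )
        chrom = sim.generate_chromatogram(p, 0)
        out = quantify_sample(
            chrom, self._curves(noise_sd=0.0), self.ANALYTES, 1e7, 1.0, self.GEOMETRY
        )
        mannitol = next(q for q in out if q.analyte == "mannitol")
        assert mannitol.pg_per_spore == 0.0
        assert mannitol.below_loq

    def test_zero_spores_rejected(self):
        chrom = sim.generate_chromatogram(sim.ChromSimParams(noise_sd=0.0), 0)
        with pytest.raises(SpectrumContentError):
            quantify_sample(chrom, {}, [], 0, 1.0, self.GEOMETRY)


class TestCompositionProportions:
    def test_three_equal_tos_without_trehalose(self):
        # composition like the Hamigera avellanea extract: 0/33/33/33
        out = composition_proportions(
            {"trehalose": 0.0, "isobemisiose": 1.0, "neosartose": 1.0,
             "fischerose": 1.0}
        )
        assert out.percents == {
            "trehalose": 0, "isobemisiose": 33, "neosartose": 33, "fischerose": 33,
        }

    def test_single_nonzero_is_hundred(self):
        out = composition_proportions({"trehalose": 4.2})
        assert out.percents["trehalose"] == 100
        assert sum(out.fractions.values()) == pytest.approx(1.0)

    @given(
        vals=st.lists(st.floats(0.01, 100.0), min_size=4, max_size=4)
    )
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one(self, vals):
        names = ("trehalose", "isobemisiose", "neosartose", "fischerose")
        out = composition_proportions(dict(zip(names, vals)))
        assert sum(out.fractions.values()) == pytest.approx(1.0, rel=1e-12)
        assert abs(sum(out.percents.values()) - 100) <= 2  # integer rounding

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            composition_proportions({"trehalose": 0.0})
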
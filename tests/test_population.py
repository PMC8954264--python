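"""Suspension accounting: number density, alpha, mass balances, sampling."""

import numpy as np
import pytest

from lipoload import (
    SizeDistribution,
    Suspension,
    Vesicle,
    concentrate,
    excluded_volume_fraction,
    lipids_per_vesicle,
    mix,
    number_density,
    sample_diameters,
)
from lipoload._units import AVOGADRO
from lipoload.geometry import core_volume, membrane_volume
from lipoload.population import read_diameters_csv, write_diameters_csv


class TestNumberDensity:
    def test_monodisperse_value(self, suspension_20mM, vesicle_100nm):
        expected = 0.020 * AVOGADRO / lipids_per_vesicle(vesicle_100nm)
        assert number_density(suspension_20mM) == pytest.approx(expected, rel=1e-12)
        assert number_density(suspension_20mM) == pytest.approx(9.53e16, rel=2e-3)

    def test_zero_lipid(self):
        s = Suspension(0.0, 500.0, SizeDistribution(100.0))
        assert number_density(s) == 0.0

    def test_lognormal_converges_to_monodisperse(self, suspension_20mM):
        """Monte-Carlo oracle: at pdi -> 0 the quadrature path must agree
        with the closed form within 0.1%."""
        s = Suspension(20.0, 500.0, SizeDistribution(100.0, 1e-6))
        nd = number_density(s)
        assert nd == pytest.approx(number_density(suspension_20mM), rel=1e-3)
        # independent Monte-Carlo estimate of E[N_lipids]
        d = sample_diameters(SizeDistribution(100.0, 1e-6), 20_000, seed=7)
        mean_lipids = np.mean([lipids_per_vesicle(Vesicle(x)) for x in d])
        assert nd == pytest.approx(0.020 * AVOGADRO / mean_lipids, rel=1e-3)


class TestAlpha:
    def test_core_value(self, suspension_20mM, vesicle_100nm):
        expected = (
            number_density(suspension_20mM) * core_volume(vesicle_100nm) * 1e-24
        )
        a = excluded_volume_fraction(suspension_20mM, "core")
        assert a == pytest.approx(expected, rel=1e-12)
        assert a == pytest.approx(0.036, abs=5e-4)

    def test_zero_lipid_gives_zero(self):
        s = Suspension(0.0, 500.0, SizeDistribution(100.0))
        assert excluded_volume_fraction(s, "core") == 0.0

    def test_membrane_zero_thickness(self):
        s = Suspension(20.0, 500.0, SizeDistribution(100.0), bilayer_thickness_nm=0.0)
        assert excluded_volume_fraction(s, "membrane") == 0.0

    def test_unphysical_alpha_fails_loudly(self):
        s = Suspension(5000.0, 500.0, SizeDistribution(300.0))
        with pytest.raises(ValueError, match="alpha"):
            excluded_volume_fraction(s, "core")

    @pytest.mark.filterwarnings("ignore:size distribution truncated")
    def test_core_plus_membrane_below_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = Suspension(
                rng.uniform(1.0, 50.0),
                500.0,
                SizeDistribution(rng.uniform(50.0, 200.0), rng.uniform(0.0, 0.3)),
            )
            total = excluded_volume_fraction(s, "core") + excluded_volume_fraction(
                s, "membrane"
            )
            assert 0.0 < total < 1.0

    def test_polydisperse_alpha_matches_monte_carlo(self):
        """Quadrature vs seeded Monte-Carlo over the same lognormal."""
        dist = SizeDistribution(100.0, 0.13)
        s = Suspension(20.0, 500.0, dist)
        a_quad = excluded_volume_fraction(s, "core")
        d = sample_diameters(dist, 200_000, seed=11)
        vols = np.array([core_volume(Vesicle(x)) for x in d])
        lips = np.array([lipids_per_vesicle(Vesicle(x)) for x in d])
        a_mc = 0.020 * AVOGADRO * vols.mean() * 1e-24 / lips.mean()
        assert a_quad == pytest.approx(a_mc, rel=5e-3)


class TestMassBalance:
    def test_concentrate_protocol_example(self):
        s = Suspension(1.0, 10_000.0, SizeDistribution(100.0))
        out = concentrate(s, 20.0, 1.0)
        assert out.lipid_concentration_mM == pytest.approx(20.0)
        assert out.volume_uL == pytest.approx(500.0)
        assert out.distribution == s.distribution

    def test_concentrate_identity_and_retention(self):
        s = Suspension(1.0, 10_000.0, SizeDistribution(100.0))
        assert concentrate(s, 1.0, 1.0) == s
        lossy = concentrate(s, 20.0, 0.792)
        assert lossy.lipid_concentration_mM == pytest.approx(15.84)

    def test_concentrate_rejects_fold_below_one(self):
        s = Suspension(1.0, 10_000.0, SizeDistribution(100.0))
        with pytest.raises(ValueError, match="fold"):
            concentrate(s, 0.5)

    def test_mole_conservation(self):
        s = Suspension(1.0, 10_000.0, SizeDistribution(100.0))
        out = concentrate(s, 20.0, 1.0)
        assert out.lipid_mol == pytest.approx(s.lipid_mol, rel=1e-12)
        mixed, _ = mix(out, 50.0, 172.0)
        assert mixed.lipid_mol == pytest.approx(s.lipid_mol, rel=1e-12)

    def test_mix_protocol_example(self, suspension_20mM):
        aliquot = suspension_20mM.aliquot(450.0)
        mixed, c_t = mix(aliquot, 50.0, 172.0)
        assert c_t == pytest.approx(17.2)
        assert mixed.lipid_concentration_mM == pytest.approx(18.0)
        assert mixed.volume_uL == pytest.approx(500.0)

    def test_mix_zero_aliquot_concentration(self, suspension_20mM):
        _, c_t = mix(suspension_20mM, 50.0, 0.0)
        assert c_t == 0.0


class TestSampling:
    def test_monodisperse_constant(self):
        d = sample_diameters(SizeDistribution(100.0), 100, seed=0)
        assert np.all(d == 100.0)

    def test_cv2_matches_pdi(self):
        d = sample_diameters(SizeDistribution(100.0, 0.13), 100_000, seed=5)
        cv2 = d.var() / d.mean() ** 2
        assert cv2 == pytest.approx(0.13, rel=0.05)
        assert d.mean() == pytest.approx(100.0, rel=0.01)

    def test_seed_determinism(self):
        dist = SizeDistribution(80.0, 0.2)
        a = sample_diameters(dist, 1000, seed=42)
        b = sample_diameters(dist, 1000, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_truncation_warns(self):
        # mean close to 2t with huge spread: mass below the valid floor
        dist = SizeDistribution(12.0, 0.9)
        with pytest.warns(UserWarning, match="rejected"):
            sample_diameters(dist, 1000, seed=0)

    def test_invalid_pdi_rejected(self):
        with pytest.raises(ValueError, match="pdi"):
            SizeDistribution(100.0, 1.0)

    def test_csv_round_trip(self, tmp_path):
        d = sample_diameters(SizeDistribution(80.0, 0.13), 50, seed=9)
        path = tmp_path / "dls.csv"
        write_diameters_csv(path, d)
        np.testing.assert_allclose(read_diameters_csv(path), d)
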
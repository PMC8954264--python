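"""The equilibration model: C_max = alpha * C_E, the supply cap, D:L surface."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lipoload import (
    Compound,
    LoadingConditions,
    SizeDistribution,
    Suspension,
    Vesicle,
    coload,
    core_volume,
    dl_surface,
    equilibrate,
    lipids_per_vesicle,
)
from lipoload._units import AVOGADRO


class TestEquilibrate:
    def test_hydrophilic_protocol_prediction(self, suspension_20mM):
        """The printed protocol (20 mM lipid, 100 nm vesicles, 17.2 mM drug)
        predicts D:L ~ 0.031 under the equal-concentration model."""
        res = equilibrate(
            suspension_20mM,
            Compound("DXR", "hydrophilic"),
            LoadingConditions(17.2, temperature_C=55.0, duration_h=1.0),
        )
        assert res.dl_ratio == pytest.approx(0.031, abs=5e-4)
        assert not res.drug_limited

    def test_zero_drug(self, suspension_20mM):
        res = equilibrate(
            suspension_20mM, Compound("DXR", "hydrophilic"), LoadingConditions(0.0)
        )
        assert res.dl_ratio == 0.0
        assert not res.drug_limited

    def test_supply_cap_for_extreme_partitioning(self, suspension_20mM):
        """A huge membrane:water partition coefficient drives alpha*C_E past
        C_T; the encapsulated amount must clip at the available drug."""
        res = equilibrate(
            suspension_20mM,
            Compound("NR", "lipophilic", partition_coefficient=1e6),
            LoadingConditions(10.0),
        )
        assert res.drug_limited
        assert res.encapsulated_mM == pytest.approx(10.0)
        assert res.c_max_mM > res.c_t_mM

    def test_negative_drug_rejected(self):
        with pytest.raises(ValueError, match="bulk_drug_concentration"):
            LoadingConditions(-1.0)

    def test_per_particle_brute_force_oracle(self, suspension_20mM, vesicle_100nm):
        """Independent per-particle chain: (vesicles/L) * (core volume in L)
        * C_T mol/L of drug inside, divided by lipid mol/L."""
        c_t = 17.2
        vesicles_per_L = (
            0.020 * AVOGADRO / lipids_per_vesicle(vesicle_100nm)
        )
        drug_mol_per_L = vesicles_per_L * core_volume(vesicle_100nm) * 1e-24 * (
            c_t * 1e-3
        )
        expected_dl = drug_mol_per_L / 0.020
        res = equilibrate(
            suspension_20mM, Compound("DXR", "hydrophilic"), LoadingConditions(c_t)
        )
        assert res.dl_ratio == pytest.approx(expected_dl, rel=1e-12)

    @given(
        c_l=st.floats(1.0, 50.0),
        d=st.floats(30.0, 300.0),
        c_t=st.floats(0.0, 100.0),
        k=st.floats(0.1, 1e5),
        lipo=st.booleans(),
    )
    @settings(max_examples=150, deadline=None)
    def test_model_identities_randomized(self, c_l, d, c_t, k, lipo):
        """On random inputs: c_max = alpha * C_E exactly, encapsulated <= C_T,
        and encapsulated + free = C_T (mole conservation)."""
        s = Suspension(c_l, 500.0, SizeDistribution(d))
        c = Compound(
            "x", "lipophilic" if lipo else "hydrophilic", partition_coefficient=k
        )
        res = equilibrate(s, c, LoadingConditions(c_t))
        assert res.c_max_mM == res.alpha * res.c_e_mM
        assert res.encapsulated_mM <= res.c_t_mM
        assert res.encapsulated_mM + res.free_mM == pytest.approx(
            res.c_t_mM, rel=1e-12, abs=1e-300
        )

    def test_dl_vanishes_with_core(self):
        """Hydrophilic D:L -> 0 as the diameter approaches twice the bilayer
        thickness (the core disappears)."""
        dls = []
        for d in (10.5, 11.0, 15.0, 50.0):
            s = Suspension(20.0, 500.0, SizeDistribution(d))
            res = equilibrate(
                s, Compound("x", "hydrophilic"), LoadingConditions(10.0)
            )
            dls.append(res.dl_ratio)
        assert dls == sorted(dls)
        assert dls[0] < 1e-4


class TestDlSurface:
    def test_hydrophilic_slice_linear_in_diameter(self, suspension_20mM):
        d = np.linspace(60.0, 200.0, 29)
        grid = dl_surface(suspension_20mM, d, [10.0], Compound("f", "hydrophilic"))
        fit = stats.linregress(d, grid.values[:, 0])
        assert fit.rvalue**2 > 0.999

    def test_lipophilic_slice_flat_in_diameter(self, suspension_20mM):
        d = np.linspace(60.0, 200.0, 29)
        grid = dl_surface(suspension_20mM, d, [10.0], Compound("nr", "lipophilic"))
        col = grid.values[:, 0]
        assert col.max() / col.min() < 1.01

    def test_linear_in_concentration_below_cap(self, suspension_20mM):
        d = np.linspace(60.0, 200.0, 8)
        g1 = dl_surface(suspension_20mM, d, [5.0], Compound("f", "hydrophilic"))
        g2 = dl_surface(suspension_20mM, d, [10.0], Compound("f", "hydrophilic"))
        np.testing.assert_allclose(2.0 * g1.values, g2.values, rtol=1e-12)

    def test_rejects_degenerate_diameters(self, suspension_20mM):
        with pytest.raises(ValueError, match="diameters"):
            dl_surface(suspension_20mM, [9.0], [10.0], Compound("f", "hydrophilic"))


class TestCoload:
    def test_two_dyes_two_phases(self, suspension_20mM):
        results = coload(
            suspension_20mM,
            [
                (Compound("fluorescein", "hydrophilic"), LoadingConditions(75.0)),
                (Compound("nile red", "lipophilic"), LoadingConditions(2.0)),
            ],
        )
        assert [r.loading_class for r in results] == ["hydrophilic", "lipophilic"]
        assert all(r.dl_ratio > 0 for r in results)

    def test_single_compound_matches_equilibrate(self, suspension_20mM):
        c = Compound("DXR", "hydrophilic")
        cond = LoadingConditions(17.2)
        (res,) = coload(suspension_20mM, [(c, cond)])
        assert res == equilibrate(suspension_20mM, c, cond)

    def test_order_permutes_results(self, suspension_20mM):
        pairs = [
            (Compound("a", "hydrophilic"), LoadingConditions(1.0)),
            (Compound("b", "lipophilic"), LoadingConditions(2.0)),
        ]
        fwd = coload(suspension_20mM, pairs)
        rev = coload(suspension_20mM, pairs[::-1])
        assert fwd == rev[::-1]
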
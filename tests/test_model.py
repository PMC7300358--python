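import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossfeed import (
    Derivatives,
    InvalidParameterError,
    InvalidStateError,
    ModelParams,
    SystemState,
    full_rhs,
    load_params,
    metabolite_rhs,
    overproducer_rhs,
    strain_rhs,
)
from crossfeed.model import PRESETS, monod, rhs_vector

# Hand-computed by direct substitution (independent spreadsheet arithmetic):
# state xL=xA=0.2, cA=cL=0.1, informed parameters.
HAND_DXL = 0.2 * 1.0 * (0.1 / 2.1) * 0.6          # 0.005714285714...
HAND_DXA = 0.2 * 2.0 * (0.1 / 1.1) * 0.6          # 0.021818181818...
HAND_DCA = 0.1 * 0.2 - 1.0 * (0.1 / 2.1) * 0.2    # 0.010476190476...
HAND_DCL = 0.1 * 0.2 - 1.0 * (0.1 / 1.1) * 0.2    # 0.001818181818...


class TestModelParams:
    def test_informed_preset_values(self, informed):
        assert (informed.r1, informed.r2) == (1.0, 2.0)
        assert (informed.kcA, informed.kcL) == (2.0, 1.0)
        assert informed.beta1 == informed.beta2 == 0.1
        assert informed.gamma1 == informed.gamma2 == 1.0
        assert informed.K == 1.0

    def test_neutral_preset_symmetric(self, neutral):
        assert neutral.r1 == neutral.r2 == 1.0
        assert neutral.kcA == neutral.kcL == 1.0

    @pytest.mark.parametrize("field", ["r1", "r2", "K", "kcA", "kcL"])
    def test_nonpositive_rate_rejected(self, field):
        with pytest.raises(InvalidParameterError):
            ModelParams(**{field: 0.0})
        with pytest.raises(InvalidParameterError):
            ModelParams(**{field: -1.0})

    def test_zero_production_allowed(self):
        p = ModelParams(beta1=0.0, beta2=0.0, gamma1=0.0, gamma2=0.0)
        assert p.beta1 == 0.0

    def test_negative_ro_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModelParams(ro=-0.1)


class TestSystemState:
    def test_negative_density_rejected(self):
        with pytest.raises(InvalidStateError):
            SystemState(xL=-0.1, xA=0.2)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidStateError):
            SystemState(xL=0.1, xA=0.2, cA=-1.0)

    def test_vector_round_trip(self):
        s = SystemState(xL=0.1, xA=0.2, xO=0.05, cA=0.3, cL=0.4, t=7.0)
        assert SystemState.from_vector(s.as_vector(), t=7.0) == s


class TestMonod:
    def test_zero_concentration(self):
        assert monod(0.0, 2.0) == 0.0

    def test_half_saturation(self):
        assert monod(1.0, 1.0) == pytest.approx(0.5)

    def test_zero_k_rejected(self):
        with pytest.raises(InvalidParameterError):
            monod(0.5, 0.0)

    def test_saturates_below_one(self):
        assert 0 < monod(1e6, 1.0) < 1.0


class TestStrainRHS:
    def test_zero_metabolites_abolish_growth(self, informed):
        d = strain_rhs(SystemState(xL=0.2, xA=0.2), informed)
        assert d.dxL == 0.0 and d.dxA == 0.0

    def test_carrying_capacity_stops_growth(self, informed):
        d = strain_rhs(SystemState(xL=0.5, xA=0.5, cA=3.0, cL=3.0), informed)
        assert d.dxL == pytest.approx(0.0, abs=1e-15)
        assert d.dxA == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_values(self, informed):
        d = strain_rhs(SystemState(xL=0.2, xA=0.2, cA=0.1, cL=0.1), informed)
        assert d.dxL == pytest.approx(HAND_DXL, rel=1e-12)
        assert d.dxA == pytest.approx(HAND_DXA, rel=1e-12)
        # frozen magnitudes from the independent arithmetic
        assert d.dxL == pytest.approx(0.005714285714, abs=1e-9)
        assert d.dxA == pytest.approx(0.021818181818, abs=1e-9)


class TestMetaboliteRHS:
    def test_no_cells_no_flux(self, informed):
        d = metabolite_rhs(SystemState(xL=0.0, xA=0.0, cA=0.4, cL=0.7), informed)
        assert d.dcA == 0.0 and d.dcL == 0.0

    def test_hand_computed_values(self, informed):
        d = metabolite_rhs(SystemState(xL=0.2, xA=0.2, cA=0.1, cL=0.1), informed)
        assert d.dcA == pytest.approx(HAND_DCA, rel=1e-12)
        assert d.dcL == pytest.approx(HAND_DCL, rel=1e-12)
        assert d.dcA == pytest.approx(0.010476190476, abs=1e-9)
        assert d.dcL == pytest.approx(0.001818181818, abs=1e-9)

    def test_no_production_no_uptake_at_zero_concentration(self):
        p = ModelParams(beta1=0.0, beta2=0.0)
        d = metabolite_rhs(SystemState(xL=0.3, xA=0.3), p)
        assert d.dcA == 0.0 and d.dcL == 0.0


class TestOverproducerRHS:
    def test_extinct_stays_extinct(self, informed):
        p = informed.replace(ro=0.5)
        d = overproducer_rhs(SystemState(xL=0.2, xA=0.2, xO=0.0), p)
        assert d.dxO == 0.0

    def test_carrying_capacity(self, informed):
        p = informed.replace(ro=0.5)
        d = overproducer_rhs(SystemState(xL=0.4, xA=0.5, xO=0.1), p)
        assert d.dxO == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_value(self, informed):
        p = informed.replace(ro=0.5)
        d = overproducer_rhs(SystemState(xL=0.2, xA=0.2, xO=0.1), p)
        assert d.dxO == pytest.approx(0.1 * 0.5 * 0.5, rel=1e-12)  # 0.025


densities = st.floats(min_value=0.0, max_value=0.33, allow_nan=False)
concentrations = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)


class TestInvariants:
    @given(xL=densities, xA=densities, xO=densities, cA=concentrations, cL=concentrations)
    @settings(max_examples=100, deadline=None)
    def test_reduction_to_two_strain(self, xL, xA, xO, cA, cL):
        """With xO = 0 and ro = 0, the three-strain RHS equals the
        two-strain RHS componentwise, machine-exactly."""
        p2 = PRESETS["informed"]
        p3 = p2.replace(ro=0.0)
        s = SystemState(xL=xL, xA=xA, xO=0.0, cA=cA, cL=cL)
        d3 = full_rhs(s, p3)
        d2s = strain_rhs(s, p2)
        d2m = metabolite_rhs(s, p2)
        assert d3.dxL == d2s.dxL
        assert d3.dxA == d2s.dxA
        assert d3.dxO == 0.0
        assert d3.dcA == d2m.dcA
        assert d3.dcL == d2m.dcL

    @given(xL=densities, xA=densities, xO=densities, cA=concentrations, cL=concentrations)
    @settings(max_examples=100, deadline=None)
    def test_growth_vanishes_at_zero_density(self, xL, xA, xO, cA, cL):
        """Each strain derivative is zero when that strain is extinct."""
        p = PRESETS["informed"].replace(ro=0.3)
        d = full_rhs(SystemState(xL=0.0, xA=xA, xO=xO, cA=cA, cL=cL), p)
        assert d.dxL == 0.0
        d = full_rhs(SystemState(xL=xL, xA=0.0, xO=xO, cA=cA, cL=cL), p)
        assert d.dxA == 0.0

    @given(a=st.floats(0, 1), b=st.floats(0, 1),
           cA=concentrations, cL=concentrations)
    @settings(max_examples=100, deadline=None)
    def test_growth_vanishes_at_capacity(self, a, b, cA, cL):
        """At total density K the logistic factor kills every strain derivative."""
        p = PRESETS["informed"].replace(ro=0.4)
        xL = a
        xA = (1.0 - a) * b
        xO = max(1.0 - xL - xA, 0.0)
        d = full_rhs(SystemState(xL=xL, xA=xA, xO=xO, cA=cA, cL=cL), p)
        assert abs(d.dxL) < 1e-12 and abs(d.dxA) < 1e-12 and abs(d.dxO) < 1e-12

    @given(xL=densities, xA=densities, cA=concentrations, cL=concentrations)
    @settings(max_examples=100, deadline=None)
    def test_no_uptake_means_nondecreasing_metabolites(self, xL, xA, cA, cL):
        p = ModelParams(gamma1=0.0, gamma2=0.0)
        d = metabolite_rhs(SystemState(xL=xL, xA=xA, cA=cA, cL=cL), p)
        assert d.dcA >= 0.0 and d.dcL >= 0.0

    @given(xL=densities, xA=densities, xO=densities,
           cA=concentrations, cL=concentrations)
    @settings(max_examples=100, deadline=None)
    def test_vector_rhs_matches_dataclass_rhs(self, xL, xA, xO, cA, cL):
        p = PRESETS["informed"].replace(ro=0.2)
        s = SystemState(xL=xL, xA=xA, xO=xO, cA=cA, cL=cL)
        fast = rhs_vector(p)(0.0, s.as_vector())
        slow = full_rhs(s, p).as_vector()
        np.testing.assert_allclose(fast, slow, rtol=0, atol=0)


class TestLoadParams:
    def test_preset_names(self):
        assert load_params("informed") == PRESETS["informed"]
        assert load_params("neutral") == PRESETS["neutral"]

    def test_unknown_preset_raises(self):
        with pytest.raises(InvalidParameterError):
            load_params("nonexistent")

    def test_dict_with_preset_override(self):
        p = load_params({"preset": "informed", "r2": 3.0})
        assert p.r2 == 3.0 and p.kcA == 2.0

    def test_unknown_keys_rejected(self):
        with pytest.raises(InvalidParameterError):
            load_params({"r1": 1.0, "bogus": 2.0})

    def test_yaml_file(self, tmp_path):
        cfg = tmp_path / "p.yaml"
        cfg.write_text("preset: neutral\nbeta1: 0.2\n")
        p = load_params(cfg)
        assert p.beta1 == 0.2 and p.r2 == 1.0

    def test_toml_file(self, tmp_path):
        cfg = tmp_path / "p.toml"
        cfg.write_text('preset = "informed"\nr1 = 1.5\n')
        p = load_params(cfg)
        assert p.r1 == 1.5 and p.r2 == 2.0

    def test_shipped_preset_files_match_code(self):
        import pathlib

        import crossfeed.model as m
        preset_dir = pathlib.Path(m.__file__).parent / "presets"
        for name in ("informed", "neutral"):
            assert load_params(preset_dir / f"{name}.yaml") == PRESETS[name]
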
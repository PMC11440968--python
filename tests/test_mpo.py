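"""Desirability transforms, MPO composite scores, and the config-driven BBB score."""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bbbscreen import (
    CNS_MPO,
    CNS_PET_MPO,
    Classification,
    DescriptorProfile,
    DesirabilityFunction,
    MpoModel,
    example_bbb_config,
    model_from_dict,
    score_bbb,
    score_mpo,
    transform_hump,
    transform_monotonic_decreasing,
)
from bbbscreen.errors import ConfigurationError, ScoringError
from bbbscreen.mpo import hump, monotonic_decreasing

CLOGP_FN = monotonic_decreasing(3.0, 5.0)
TPSA_FN = hump(20.0, 40.0, 90.0, 120.0)


class TestTransforms:
    @pytest.mark.parametrize("value,expected", [
        (2.5, 1.0),   # in the desirable region
        (3.0, 1.0),   # boundary: exactly at desirable_max scores 1
        (6.0, 0.0),   # past the undesirable cutoff
        (4.0, 0.5),   # linear midpoint of the ramp
        (5.0, 0.0),   # ramp formula evaluates to 0 at undesirable_min
    ])
    def test_monotonic_decreasing_values(self, value, expected):
        assert transform_monotonic_decreasing(value, CLOGP_FN) == pytest.approx(expected)

    @pytest.mark.parametrize("value,expected", [
        (65.0, 1.0),    # central window
        (90.0, 1.0),    # closed right end of the window
        (10.0, 0.0),    # low tail
        (20.0, 0.0),    # boundary of the low tail (<=)
        (125.0, 0.0),   # high tail
        (105.0, 0.5),   # midpoint of the falling ramp
        (30.0, 0.5),    # midpoint of the rising ramp
        (40.0, 1.0),    # rising ramp meets the window continuously
    ])
    def test_hump_values(self, value, expected):
        assert transform_hump(value, TPSA_FN) == pytest.approx(expected)

    def test_malformed_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            monotonic_decreasing(5.0, 3.0)
        with pytest.raises(ConfigurationError):
            hump(40.0, 20.0, 90.0, 120.0)
        with pytest.raises(ConfigurationError):
            DesirabilityFunction("sigmoid", desirable_max=1, undesirable_min=2)

    @given(st.floats(-50, 200))
    def test_outputs_in_unit_interval(self, value):
        assert 0.0 <= transform_monotonic_decreasing(value, CLOGP_FN) <= 1.0
        assert 0.0 <= transform_hump(value, TPSA_FN) <= 1.0

    @given(st.floats(-50, 200), st.floats(0, 50))
    def test_monotonic_decreasing_is_non_increasing(self, value, step):
        assert transform_monotonic_decreasing(value + step, CLOGP_FN) <= (
            transform_monotonic_decreasing(value, CLOGP_FN) + 1e-12
        )

    @given(st.floats(-50, 65), st.floats(0, 50))
    def test_hump_non_decreasing_up_to_mode(self, value, step):
        # unimodality, rising side (mode region starts at desirable_lo)
        v2 = min(value + step, 65.0)
        assert transform_hump(v2, TPSA_FN) >= transform_hump(value, TPSA_FN) - 1e-12

    @given(st.floats(90, 250), st.floats(0, 50))
    def test_hump_non_increasing_past_mode(self, value, step):
        assert transform_hump(value + step, TPSA_FN) <= (
            transform_hump(value, TPSA_FN) + 1e-12
        )


def mpo_profile(mw, clogp, clogd, tpsa, hbd, pka):
    return DescriptorProfile(mw=mw, clogp=clogp, clogd74=clogd, tpsa=tpsa,
                             hbd=hbd, pka_basic=pka)


class TestScoreMpo:
    def test_fully_desirable_profile_scores_six(self):
        s = score_mpo(mpo_profile(300, 2, 1, 65, 0, 7), CNS_MPO)
        assert s.total == pytest.approx(6.0)
        assert s.classification is Classification.CNS_PLUS

    def test_fully_undesirable_profile_scores_zero(self):
        s = score_mpo(mpo_profile(600, 6, 5, 10, 4, 11), CNS_MPO)
        assert s.total == pytest.approx(0.0)
        assert s.classification is Classification.CNS_MINUS

    def test_hand_summed_mixed_profile(self):
        # components: mw 0.5, clogp 0.5, clogd 0.5, tpsa 1.0, hbd 0.5, pka 0.5
        s = score_mpo(mpo_profile(430, 4, 3, 65, 2, 9), CNS_MPO)
        assert s.total == pytest.approx(3.5)
        assert s.components["tpsa"] == pytest.approx(1.0)
        assert s.classification is Classification.CNS_MINUS

    def test_threshold_is_strict(self):
        # exactly 4.0 under cns_mpo classifies CNS-
        s = score_mpo(mpo_profile(430, 4, 3, 65, 2, 7), CNS_MPO)
        assert s.total == pytest.approx(4.0)
        assert s.classification is Classification.CNS_MINUS

    def test_missing_pka_imputed_as_one_and_flagged(self):
        s = score_mpo(
            DescriptorProfile(mw=300, clogp=2, clogd74=1, tpsa=65, hbd=0),
            CNS_MPO,
        )
        assert s.components["pka_basic"] == 1.0
        assert any("pka_basic" in f for f in s.flags)

    def test_missing_core_descriptor_raises(self):
        with pytest.raises(ScoringError, match="clogd74"):
            score_mpo(DescriptorProfile(mw=300, clogp=2, tpsa=65, hbd=0), CNS_MPO)

    def test_pet_model_is_tighter(self):
        # inside cns_mpo's desirable space but outside the PET ranges
        s_drug = score_mpo(mpo_profile(340, 3.0, 2.0, 70, 0, 7.8), CNS_MPO)
        s_pet = score_mpo(mpo_profile(340, 3.0, 2.0, 70, 0, 7.8), CNS_PET_MPO)
        assert s_drug.total == pytest.approx(6.0)
        assert s_pet.total < 6.0

    @given(
        mw=st.floats(100, 800), clogp=st.floats(-5, 9),
        clogd=st.floats(-5, 9), tpsa=st.floats(0, 250),
        hbd=st.integers(0, 8), pka=st.floats(0, 14),
    )
    def test_total_bounded_and_componentwise(self, mw, clogp, clogd, tpsa, hbd, pka):
        for model in (CNS_MPO, CNS_PET_MPO):
            s = score_mpo(mpo_profile(mw, clogp, clogd, tpsa, hbd, pka), model)
            assert 0.0 <= s.total <= 6.0
            assert all(0.0 <= v <= 1.0 for v in s.components.values())
            assert s.total == pytest.approx(sum(s.components.values()))

    def test_component_order_does_not_change_total(self):
        p = mpo_profile(430, 4, 3, 65, 2, 9)
        rng = random.Random(7)
        comps = list(CNS_MPO.components)
        for _ in range(5):
            rng.shuffle(comps)
            permuted = MpoModel("perm", tuple(comps), 4.0)
            assert score_mpo(p, permuted).total == pytest.approx(
                score_mpo(p, CNS_MPO).total
            )

    def test_custom_model_from_dict(self):
        spec = {
            "name": "tiny",
            "cns_plus_threshold": 1.0,
            "components": [
                {"descriptor": "mw", "kind": "monotonic_decreasing",
                 "desirable_max": 360, "undesirable_min": 500},
                {"descriptor": "tpsa", "kind": "hump", "undesirable_lo": 20,
                 "desirable_lo": 40, "desirable_hi": 90, "undesirable_hi": 120},
            ],
        }
        model = model_from_dict(spec)
        s = score_mpo(DescriptorProfile(mw=300, tpsa=65), model)
        assert s.total == pytest.approx(2.0)
        with pytest.raises(ConfigurationError):
            model_from_dict({"name": "broken"})


class TestBbbScore:
    def _profile(self):
        return DescriptorProfile(mw=400.0, hbd=3, hba=5, aromatic_rings=2,
                                 heavy_atoms=28, tpsa=60.0, pka_basic=8.0)

    def test_constant_one_config_scores_five(self):
        config = {
            d: {"pieces": [{"lo": -1e6, "hi": 1e6, "coeffs": [1.0]}],
                "weight": 1.0}
            for d in ("aromatic_rings", "heavy_atoms", "mwhbn", "tpsa", "pka")
        }
        config["id"] = "const1"
        assert score_bbb(self._profile(), config).total == pytest.approx(5.0)

    def test_constant_zero_config_scores_zero(self):
        config = {
            d: {"pieces": [{"lo": -1e6, "hi": 1e6, "coeffs": [0.0]}]}
            for d in ("aromatic_rings", "heavy_atoms", "mwhbn", "tpsa", "pka")
        }
        assert score_bbb(self._profile(), config).total == 0.0

    def test_mwhbn_follows_configured_exponent(self):
        # identity function on mwhbn, zero elsewhere: score == HBN / MW**e
        config = {
            d: {"pieces": [{"lo": -1e6, "hi": 1e6, "coeffs": [0.0]}]}
            for d in ("aromatic_rings", "heavy_atoms", "tpsa", "pka")
        }
        config["mwhbn"] = {"pieces": [{"lo": -1e6, "hi": 1e6, "coeffs": [0.0, 1.0]}]}
        config["mwhbn_exponent"] = 0.5
        p = DescriptorProfile(mw=400.0, hbd=3, hba=5, aromatic_rings=2,
                              heavy_atoms=28, tpsa=60.0)
        expected = 8 / math.sqrt(400.0)
        assert score_bbb(p, config).total == pytest.approx(expected, rel=1e-12)
        config["mwhbn_exponent"] = 1.0
        assert score_bbb(p, config).total == pytest.approx(8 / 400.0, rel=1e-12)

    def test_absent_config_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="config"):
            score_bbb(self._profile(), None)

    def test_example_config_bounded_and_provenanced(self):
        result = score_bbb(self._profile(), example_bbb_config())
        assert 0.0 <= result.total <= 5.0
        assert result.config_id == "synthetic-example"
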
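"""Brain-disposition equations, logBB regressions and the CNS access score."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bbbscreen import (
    BrainDisposition,
    Classification,
    CnsAccessInputs,
    DescriptorProfile,
    PenetranceCategory,
    PerfusionExperiment,
    classify_logbb,
    cns_access,
    kin_from_perfusion,
    logbb_from_concentrations,
    predict_logbb,
    ps_renkin_crone,
)
from bbbscreen.errors import ConfigurationError, DomainError, ScoringError


class TestConcentrationRatio:
    @pytest.mark.parametrize("c_brain,c_blood,expected", [
        (1.0, 1.0, 0.0),
        (10.0, 1.0, 1.0),
        (0.5, 1.0, math.log10(0.5)),  # -0.3010...
    ])
    def test_log_ratio(self, c_brain, c_blood, expected):
        got = logbb_from_concentrations(BrainDisposition(c_brain, c_blood))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_non_positive_concentration_rejected(self):
        with pytest.raises(DomainError):
            logbb_from_concentrations(BrainDisposition(0.0, 1.0))
        with pytest.raises(DomainError):
            logbb_from_concentrations(BrainDisposition(1.0, -2.0))


class TestPerfusion:
    def test_zero_uptake_gives_zero_ps(self):
        assert ps_renkin_crone(PerfusionExperiment(flow=1.0, kin=0.0)) == 0.0

    def test_half_extraction(self):
        ps = ps_renkin_crone(PerfusionExperiment(flow=1.0, kin=0.5))
        assert ps == pytest.approx(math.log(2), rel=1e-12)

    def test_flow_limited_uptake_is_domain_error(self):
        with pytest.raises(DomainError):
            ps_renkin_crone(PerfusionExperiment(flow=1.0, kin=1.0))

    @pytest.mark.parametrize("q_br,c_pf,t,expected", [
        (2.0, 1.0, 4.0, 0.5),
        (0.0, 1.0, 5.0, 0.0),
        (3.0, 2.0, 3.0, 0.5),
    ])
    def test_kin_arithmetic(self, q_br, c_pf, t, expected):
        e = PerfusionExperiment(q_br=q_br, c_pf=c_pf, t_perfusion=t)
        assert kin_from_perfusion(e) == pytest.approx(expected, rel=1e-12)

    def test_zero_denominators_rejected(self):
        with pytest.raises(DomainError):
            kin_from_perfusion(PerfusionExperiment(q_br=1, c_pf=0, t_perfusion=1))

    @given(
        q_br=st.floats(0.0, 10.0),
        c_pf=st.floats(0.1, 10.0),
        t=st.floats(0.1, 30.0),
        flow=st.floats(0.5, 5.0),
    )
    def test_perfusion_roundtrip_recovers_kin(self, q_br, c_pf, t, flow):
        """Kin -> PS -> (numeric inversion) -> Kin to 1e-9 relative tolerance."""
        kin = kin_from_perfusion(
            PerfusionExperiment(q_br=q_br, c_pf=c_pf, t_perfusion=t)
        )
        if not kin < flow:
            return  # outside the Renkin-Crone domain
        ps = ps_renkin_crone(PerfusionExperiment(flow=flow, kin=kin))
        # closed-form inversion cross-checked by bisection
        recovered = flow * (1.0 - math.exp(-ps / flow))
        lo, hi = 0.0, flow * (1 - 1e-15)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if ps_renkin_crone(PerfusionExperiment(flow=flow, kin=mid)) < ps:
                lo = mid
            else:
                hi = mid
        assert recovered == pytest.approx(kin, rel=1e-9, abs=1e-12)
        assert 0.5 * (lo + hi) == pytest.approx(kin, rel=1e-9, abs=1e-9)


class TestRegressions:
    @pytest.mark.parametrize("model_id,profile,expected", [
        ("vilar_eq6", DescriptorProfile(clogp=0.0, tpsa=0.0), -0.3462),
        ("vilar_eq7",
         DescriptorProfile(clogp=0.0, tpsa=0.0, n_acid_base=0), 2.3420),
        ("clark_eq5", DescriptorProfile(psa=0.0, tpsa=0.0, clogp=0.0), 0.139),
        ("kansy_eq4", DescriptorProfile(psa=0.0, tpsa=0.0, molvol=0.0), 1.643),
    ])
    def test_intercepts_exact(self, model_id, profile, expected):
        assert predict_logbb(model_id, profile).value == expected

    @pytest.mark.parametrize("model_id,profile,expected", [
        # hand-computed: 0.5159*2 - 0.0277*50 - 0.3462
        ("vilar_eq6", DescriptorProfile(clogp=2.0, tpsa=50.0), -0.6994),
        # -0.021*50 - 0.003*300 + 1.643
        ("kansy_eq4", DescriptorProfile(psa=50.0, tpsa=50.0, molvol=300.0), -0.307),
        # -0.0148*60 + 0.152*2.5 + 0.139 = -0.888 + 0.38 + 0.139
        ("clark_eq5", DescriptorProfile(psa=60.0, tpsa=60.0, clogp=2.5), -0.369),
    ])
    def test_worked_values(self, model_id, profile, expected):
        assert predict_logbb(model_id, profile).value == pytest.approx(
            expected, abs=1e-12
        )

    def test_vilar_classification_semantics(self):
        plus = predict_logbb("vilar_eq6", DescriptorProfile(clogp=3.0, tpsa=10.0))
        assert plus.value > 0
        assert plus.classification is Classification.CNS_PLUS
        minus = predict_logbb("vilar_eq6", DescriptorProfile(clogp=0.0, tpsa=50.0))
        assert minus.classification is Classification.CNS_MINUS
        na = predict_logbb("clark_eq5", DescriptorProfile(psa=50.0, tpsa=50.0, clogp=1.0))
        assert na.classification is Classification.NOT_APPLICABLE

    def test_missing_descriptor_raises(self):
        with pytest.raises(ScoringError, match="molvol"):
            predict_logbb("kansy_eq4", DescriptorProfile(psa=50.0, tpsa=50.0))

    def test_unknown_model_raises(self):
        with pytest.raises(ConfigurationError):
            predict_logbb("abraham", DescriptorProfile(tpsa=50.0))

    @given(
        clogp=st.floats(-5, 10), tpsa=st.floats(0, 250),
        scale=st.floats(0.1, 3.0),
    )
    def test_linearity_superposition(self, clogp, tpsa, scale):
        """Each regression responds additively per coefficient."""
        from bbbscreen.logbb import LOGBB_MODELS

        coeffs, intercept = LOGBB_MODELS["vilar_eq6"]
        base = predict_logbb("vilar_eq6", DescriptorProfile(clogp=clogp, tpsa=tpsa))
        scaled = predict_logbb(
            "vilar_eq6", DescriptorProfile(clogp=clogp * scale, tpsa=tpsa * scale)
        )
        assert scaled.value - intercept == pytest.approx(
            scale * (base.value - intercept), rel=1e-9, abs=1e-9
        )


class TestClassifyAndAccess:
    @pytest.mark.parametrize("logbb,expected", [
        (0.1, Classification.CNS_PLUS),
        (0.0, Classification.CNS_MINUS),   # boundary goes to the negative class
        (-0.5, Classification.CNS_MINUS),
    ])
    def test_logbb_threshold_strict(self, logbb, expected):
        assert classify_logbb(logbb) is expected

    @pytest.mark.parametrize("lpf,lbb,score,category,binary", [
        (0.0, 0.0, 0.0, PenetranceCategory.PENETRANT, Classification.CNS_PLUS),
        (-2.0, -1.0, -3.0, PenetranceCategory.WEAK_PENETRANT, Classification.CNS_PLUS),
        (-3.0, -1.0, -4.0, PenetranceCategory.NON_PENETRANT, Classification.CNS_MINUS),
        (-3.5, 0.0, -3.5, PenetranceCategory.NON_PENETRANT, Classification.CNS_MINUS),
    ])
    def test_access_bands(self, lpf, lbb, score, category, binary):
        res = cns_access(CnsAccessInputs(lpf, lbb))
        assert res.score == pytest.approx(score)
        assert res.category is category
        assert res.classification is binary

    @given(st.floats(-10, 5))
    def test_bands_exhaustive_and_exclusive(self, score):
        res = cns_access(CnsAccessInputs(score, 0.0))
        in_non = res.score <= -3.50
        in_weak = -3.50 < res.score <= -3.0
        in_pen = res.score > -3.0
        assert [in_non, in_weak, in_pen].count(True) == 1
        assert res.category is {
            0: PenetranceCategory.NON_PENETRANT,
            1: PenetranceCategory.WEAK_PENETRANT,
            2: PenetranceCategory.PENETRANT,
        }[[in_non, in_weak, in_pen].index(True)]
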
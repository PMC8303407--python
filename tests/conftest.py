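import pytest
from hypothesis import HealthCheck, assume, settings
from hypothesis import strategies as st

from ureakin import (
    PatientParameters,
    TreatmentParameters,
    UnsupportedRegimeError,
    ode_coefficients,
    resolve_treatment,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.filter_too_much, HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def standard_patient() -> PatientParameters:
    """Standard adult scenario: 36 L body fluid split 4:6, Cs = 80 mg/dL,
    S = 4 mg/min, Ah = 500 mL/min (eps derived exactly)."""
    return PatientParameters(
        v_ex0=14400.0, v_in0=21600.0, eps=None, c_s=80.0, s_prod=4.0, ah=500.0
    )


@pytest.fixture
def standard_treatment() -> TreatmentParameters:
    """K = 200 mL/min for 240 min, 20 mL/min ultrafiltration, refilling
    fixed at its constant-ratio estimate of 12 mL/min."""
    return TreatmentParameters(k_clear=200.0, t_end=240.0, omega_f=20.0, omega_pl=12.0)


@st.composite
def scenarios(draw):
    """Feasible random (patient, treatment) pairs for property tests."""
    v_ex0 = draw(st.floats(8000, 20000))
    v_in0 = draw(st.floats(12000, 30000))
    ah = draw(st.floats(100, 2000))
    c_s = draw(st.floats(10, 150))
    s_prod = draw(st.floats(0, 10))
    k = draw(st.floats(80, 400))
    t_end = draw(st.floats(120, 300))
    omega_f = draw(st.floats(0, 25))
    assume(abs(k - omega_f) > 1.0)
    patient = PatientParameters(
        v_ex0=v_ex0, v_in0=v_in0, eps=None, c_s=c_s, s_prod=s_prod, ah=ah
    )
    treat = resolve_treatment(
        patient, TreatmentParameters(k_clear=k, t_end=t_end, omega_f=omega_f)
    )
    assume(patient.v_ex0 - (treat.omega_f - treat.omega_pl) * t_end > 100.0)
    assume(patient.v_in0 - treat.omega_pl * t_end > 100.0)
    try:
        ode_coefficients(patient, treat)
    except UnsupportedRegimeError:
        assume(False)
    return patient, treat
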
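import hypothesis.strategies as st
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def log_uniform(lo_exp: float, hi_exp: float):
    """Strategy for positive reals spread uniformly in log10 space."""
    return st.floats(lo_exp, hi_exp).map(lambda e: 10.0 ** e)


def concentrations():
    """Total concentrations spanning picomolar to 10 mM."""
    return log_uniform(-12, -2)


def dissociation_constants():
    """KDs spanning picomolar to millimolar."""
    return log_uniform(-12, -3)
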
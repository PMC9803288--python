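import pytest
from hypothesis import HealthCheck, settings

from crosswise.io import load_study_fixtures

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Published per-question results (percent estimate, G2, GOF p-value,
# DQ percent or None, z statistic or None) used as reference values.
TABLE2 = {
    "Drug use1-Q1": (26.2, 6.77, 0.009, None, None),
    "Drug use1-Q2": (50.2, 0.09, 0.767, None, None),
    "Drug use1-Q3": (43.4, 0.11, 0.740, None, None),
    "Drug use1-Q4": (16.2, 4.27, 0.039, None, None),
    "Drug use1-S1": (33.5, 1.28, 0.258, None, None),
    "Drug use1-S2": (46.4, 1.67, 0.197, None, None),
    "Drug use1-S3": (52.5, 0.44, 0.507, None, None),
    "Drug use1-S4": (12.3, 7.65, 0.006, None, None),
    "Covid-F1": (33.4, 3.26, 0.071, 9.8, 7.31),
    "Covid-F2": (29.7, 4.56, 0.033, 13.8, 4.80),
    "Covid-F3": (35.6, 0.07, 0.784, 33.9, 0.45),
    "Covid-F4": (28.7, 0.01, 0.915, 17.2, 3.39),
    "Covid-J1": (31.1, 0.41, 0.521, 10.9, 6.17),
    "Covid-J2": (28.6, 0.09, 0.764, 13.2, 4.64),
    "Covid-J3": (36.8, 0.83, 0.362, 25.6, 3.07),
    "Covid-J4": (33.6, 3.97, 0.046, 6.9, 8.45),
    "Drug use2-Q1": (21.0, 16.46, 0.000, 20.5, 0.19),
    "Drug use2-Q2": (44.4, 0.28, 0.596, 46.4, -0.63),
    "Drug use2-Q3": (49.1, 0.04, 0.843, 39.0, 3.23),
    "Drug use2-Q4": (3.8, 0.31, 0.580, 4.4, -0.27),
}


@pytest.fixture(scope="session")
def fixtures():
    return load_study_fixtures()


@pytest.fixture(scope="session")
def questions(fixtures):
    """Map from question label to its FixtureQuestion."""
    return {q.label: q for fx in fixtures for q in fx.questions}
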
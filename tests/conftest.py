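import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lacerisk import (
    CharlsonExtractor,
    build_default_dictionary,
    generate_cohort,
    get_profile,
    records_to_frame,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dictionary():
    return build_default_dictionary()


@pytest.fixture(scope="session")
def extractor(dictionary):
    return CharlsonExtractor(dictionary=dictionary).fit()


@pytest.fixture(scope="session")
def small_general_cohort():
    """A 400-record synthetic general-surgery cohort (fixed seed)."""
    return generate_cohort(get_profile("general", n=400), seed=2024)


@pytest.fixture(scope="session")
def small_general_frame(small_general_cohort) -> pd.DataFrame:
    return records_to_frame(small_general_cohort)


@pytest.fixture(scope="session")
def scored_general_frame(small_general_frame, extractor) -> pd.DataFrame:
    from lacerisk import LaceScorer

    frame = small_general_frame.copy()
    frame["cci"] = extractor.transform(frame).ravel()
    comp = LaceScorer().fit().transform(frame)
    return pd.concat([frame, comp], axis=1)
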
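from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

import greycast as gc

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def study_series() -> dict[str, gc.AnnualSeries]:
    """The six bundled country series, keyed by country name."""
    return {s.label: s for s in gc.load_study_series()}


@pytest.fixture(scope="session")
def published_ndgm_columns() -> pd.DataFrame:
    """Published per-year NDGM simulated values, transcribed as test vectors.

    One garbled 2019 cell (USA) is omitted.  These are expected outputs for
    comparison only, never inputs to any computation.
    """
    return pd.read_csv(DATA_DIR / "printed_ndgm_columns.csv")


@pytest.fixture(scope="session")
def study_reports(study_series) -> gc.ReportBundle:
    """Full default-configuration pipeline run on the bundled data."""
    return gc.run_full_report(study_series.values())
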
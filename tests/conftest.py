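import dataclasses

import pandas as pd
import pytest

from mortlink import GoldSpec, SourceSpec, calibrated_config
from mortlink.pipeline import run_study


def perfect_config(seed=0, n_patients=800):
    """Every source captures every death with exact dates and clean ids."""
    specs = {sid: SourceSpec(sid, capture_prob=1.0)
             for sid in ("EHR", "CDD1", "SSDI", "ABS")}
    cfg = calibrated_config(seed=seed, n_patients=n_patients)
    return dataclasses.replace(
        cfg, source_specs=specs, ehr_practice_concentration=None,
        gold_spec=GoldSpec(capture_prob=1.0, class_probs={"exact": 1.0},
                           likely_false_rate=0.0))


def clean_config(seed=0, n_patients=2000):
    """Calibrated error rates but no identifier corruption or heterogeneity."""
    cfg = calibrated_config(seed=seed, n_patients=n_patients)
    specs = {sid: dataclasses.replace(spec, id_corruption_rate=0.0)
             for sid, spec in cfg.source_specs.items()}
    return dataclasses.replace(cfg, source_specs=specs,
                               ehr_practice_concentration=None)


@pytest.fixture(scope="session")
def calibrated_study():
    """One moderate calibrated run shared across read-only tests."""
    return run_study(calibrated_config(seed=11, n_patients=3000))


@pytest.fixture(scope="session")
def perfect_study():
    return run_study(perfect_config(seed=3))


@pytest.fixture
def three_patients():
    """Tiny cohort for enumerating the linkage passes by hand."""
    return pd.DataFrame({
        "patient_id": ["P1", "P2", "P3"],
        "first_name": ["Alice", "Bob", "Carol"],
        "last_name": ["Smith", "Jones", "Smith"],
        "birth_date": pd.to_datetime(
            ["1950-03-04", "1960-05-06", "1950-03-04"]),
        "state": ["NY", "CA", "TX"],
    })
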
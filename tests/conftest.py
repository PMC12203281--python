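import logging

import numpy as np
import pytest

from hichkit import emr_synth as es
from hichkit import hws, pipeline

logging.getLogger("hichkit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def seed_graph():
    return pipeline.load_default_graph()


@pytest.fixture(scope="session")
def ruleset():
    return hws.load_ruleset()


@pytest.fixture
def make_profile():
    """Factory for a moderate baseline profile with overridable fields."""

    def factory(**kw):
        base = dict(
            age=65, sex="male", gcs_total=15, sbp=185, dbp=95,
            pupils="bilateral-equal-reactive", airway="patent", spo2=99,
            hematoma_location="basal-ganglia", hematoma_volume=5.0,
            midline_shift=0.0, ventricular_compression=False,
            intraventricular_extension=False,
            history=frozenset({"hypertension"}), suspicion=frozenset())
        base.update(kw)
        return es.PatientProfile(**base).validate()

    return factory


@pytest.fixture(scope="session")
def small_corpus():
    """60 clean annotated documents with matched profiles."""
    return es.generate_corpus(60, seed=13)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
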
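import numpy as np
import pandas as pd
import pytest

from ecog_biomarkers.core_model import ChannelInfo, Recording, StageSegment, make_biomarker_rows
from ecog_biomarkers.synthetic_data import SimConfig, generate_cohort

ALL_STAGE_CLASS = [
    (s, c) for s in ("Iso", "Sev2", "Sev3", "Sev4", "SWS") for c in ("normative", "epileptogenic")
]


def const_map(v):
    return {k: v for k in ALL_STAGE_CLASS}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(samples, fs=1000.0, patient="P01", stages=None, **channel_kw):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    meta = [ChannelInfo(label=f"C{i + 1:02d}", patient_id=patient, **channel_kw)
            for i in range(samples.shape[0])]
    if stages is None:
        stages = [StageSegment("Iso", 0, samples.shape[1])]
    return Recording(samples, fs, meta, stages)


@pytest.fixture
def tiny_cohort():
    """A 2-patient, 6-channel cohort with short stages, shared across tests."""
    sim = SimConfig(
        n_patients=2,
        n_channels_per_patient=6,
        frac_epileptogenic=0.34,
        frac_two_stage=1.0,
        edge_density=0.25,
        stage_schedule=[("Iso", 90.0), ("Sev2", 60.0), ("Sev3", 60.0), ("Sev4", 60.0), ("SWS", 60.0)],
        seed=77,
    )
    recordings, truth = generate_cohort(sim)
    return sim, recordings, truth


def stats_table(spec_rows):
    """Build a biomarker table from (patient_kw, channel, stage, epoch, biomarker, value) tuples."""
    rows = []
    for patient_kw, channel, stage, epoch, biomarker, value in spec_rows:
        info = ChannelInfo(label=channel, **patient_kw)
        rows.extend(make_biomarker_rows(info, stage, epoch, {biomarker: value}))
    return pd.DataFrame(rows)
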
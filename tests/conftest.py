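import warnings

import numpy as np
import pytest

import brainwin as bw

# lightgbm models are fitted on DataFrames-free arrays throughout
warnings.filterwarnings("ignore", message="X does not have valid feature names")


@pytest.fixture(scope="session")
def toy_acq() -> bw.AcquisitionSpec:
    return bw.AcquisitionSpec()


@pytest.fixture(scope="session")
def toy_sig() -> bw.ClassSignalSpec:
    return bw.ClassSignalSpec()


@pytest.fixture(scope="session")
def default_noise() -> bw.NoiseSpec:
    return bw.NoiseSpec()


@pytest.fixture(scope="session")
def clean_noise() -> bw.NoiseSpec:
    """No stochastic nuisance at all: pure class signal on the baseline."""
    return bw.NoiseSpec(white_sd=0.0, background_amp=0.0, drift_amp=0.0)


@pytest.fixture(scope="session")
def study_cohort(toy_acq, toy_sig, default_noise):
    """The 40-subject study-condition cohort, preprocessed and QC'd once."""
    records, vols, traces = bw.generate_cohort(
        toy_acq, toy_sig, default_noise, n_per_class=20, sites=["A", "B"], seed=11
    )
    cfg = bw.PreprocConfig()
    pvols = {}
    for rec in records:
        vol, fd, qc = bw.preprocess_subject(
            vols[rec.subject_id], traces[rec.subject_id], cfg
        )
        rec.mean_fd, rec.qc_pass = fd.mean_fd, qc
        pvols[rec.subject_id] = vol
    return records, pvols


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A cheaply trained pipeline on 8 subjects, for contract tests."""
    acq = bw.AcquisitionSpec(shape=(8, 8, 6), t=50)
    sig = bw.ClassSignalSpec(blob_center=(4, 4, 3), blob_radius=1.5)
    noise = bw.NoiseSpec()
    records, vols, _ = bw.generate_cohort(
        acq, sig, noise, n_per_class=4, sites=["A"], seed=3
    )
    config = bw.toy_pipeline_config(epochs=1, stage1_window_stride=10)
    config = bw.PipelineConfig(
        spatial=config.spatial,
        temporal=config.temporal,
        window=config.window,
        gbdt=bw.GBDTConfig(n_trees=10),
        train=config.train,
    )
    model = bw.train_pipeline(records, config, seed=4, volumes=vols)
    return model, records, vols
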
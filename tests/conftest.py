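import numpy as np
import pytest

from diaforge.io_formats import parse_detection_report, write_detection_report
from diaforge.pipeline import prepare_training_data
from diaforge.synthetic import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """Small interference-free simulated run."""
    return simulate_dataset(
        SyntheticConfig(n_peptides=60, n_proteins=25, interference_fraction=0.0, seed=42)
    )


@pytest.fixture(scope="session")
def interfered_dataset():
    """Small run with 30% of fragment peaks overlapped by co-eluters."""
    return simulate_dataset(
        SyntheticConfig(n_peptides=80, n_proteins=25, interference_fraction=0.3, seed=7)
    )


def detections_of(dataset, tmp_path, q_max=0.01):
    path = tmp_path / "report.tsv"
    write_detection_report(dataset.report_rows, str(path))
    return parse_detection_report(str(path), q_max=q_max)


@pytest.fixture(scope="session")
def clean_prepared(clean_dataset, tmp_path_factory):
    dets = detections_of(clean_dataset, tmp_path_factory.mktemp("clean"))
    return prepare_training_data(clean_dataset.run, dets)


@pytest.fixture(scope="session")
def interfered_prepared(interfered_dataset, tmp_path_factory):
    dets = detections_of(interfered_dataset, tmp_path_factory.mktemp("intf"))
    return prepare_training_data(interfered_dataset.run, dets)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
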
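import numpy as np
import pytest
from hypothesis import settings

from prednts.ensemble import PAPER_WEIGHTS, PredNTS
from prednts.sequence_io import SiteWindow, extract_windows
from prednts.synthetic import fixture_small, labelled_windows

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_window(residues: str, protein_id: str = "p", position: int = 1) -> SiteWindow:
    return SiteWindow(protein_id=protein_id, center_position=position, residues=residues)


@pytest.fixture(scope="session")
def fixture_data():
    proteins, sites, manifest = fixture_small()
    return proteins, sites, manifest


@pytest.fixture(scope="session")
def fixture_windows(fixture_data):
    proteins, sites, _ = fixture_data
    return labelled_windows(proteins, sites, w=5)


@pytest.fixture(scope="session")
def tiny_model(fixture_windows):
    """A small fitted ensemble shared by round-trip and prediction tests."""
    est = PredNTS(
        w=5, K_values=(1,), feature_selection=False, n_trees=60,
        cv_folds=3, weights=PAPER_WEIGHTS, random_state=7,
    )
    est.fit(fixture_windows)
    return est
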
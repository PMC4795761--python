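import numpy as np
import pytest

import beeallometry as ba


@pytest.fixture(scope="session")
def study_means():
    """Synthetic species-means table emulating the coefficient-fitting study:
    5 families x 20 species, packaged coefficients as truth, noise calibrated
    to the reported interspecific model R^2 values."""
    return ba.generate_interspecific(ba.study_config(seed=1))


@pytest.fixture(scope="session")
def study_means_frame(study_means):
    return ba.io.means_to_frame(study_means)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def specimen_csv(tmp_path):
    """A small, well-formed 3-row specimen table on disk."""
    p = tmp_path / "specimens.csv"
    p.write_text(
        "species,family,sex_caste,it_mm,glossa_mm,prementum_mm,proboscis_mm\n"
        "Bombus impatiens,Apidae,worker,4.5,7.1,4.4,11.5\n"
        "Andrena nasonii,Andrenidae,female,1.8,0.5,1.4,1.9\n"
        "Halictus ligatus,Halictidae,female,1.6,0.7,1.5,2.2\n"
    )
    return p
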
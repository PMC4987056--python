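import warnings

import numpy as np
import pytest

from asphyxomics.cohort import (default_concentration_model, default_panel,
                                sample_cohort, sample_concentrations,
                                simple_design)
from asphyxomics.preprocess import PreprocessConfig, preprocess_pipeline
from asphyxomics.quantify import peak_mask_windows, quantify_cohort
from asphyxomics.render import AcquisitionParams, render_cohort

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def plasma_panel():
    return default_panel("plasma")


@pytest.fixture(scope="session")
def urine_panel():
    return default_panel("urine")


@pytest.fixture(scope="session")
def plasma_model():
    return default_concentration_model("plasma")


@pytest.fixture(scope="session")
def urine_model():
    return default_concentration_model("urine")


#: identified plasma signals whose windows do not collide with a close
#: neighbour; used for tight noiseless recovery checks
SEPARATED_PLASMA = [
    "Lactate", "Glucose", "Alanine", "Hypoxanthine", "Fumarate", "Formate",
    "Acetate", "Choline", "Trimethylamine", "Tyrosine", "Phenylalanine",
    "Proline",
]


def make_cohort(material, n, seed, timepoints=("t1",), panel=None,
                model=None, noiseless=False, acq=AcquisitionParams()):
    """Generate truth + rendered spectra for a single-group cohort."""
    design = simple_design(n, timepoints=timepoints, materials=(material,))
    animals, manifest = sample_cohort(design, seed)
    model = model or default_concentration_model(material)
    panel = panel or default_panel(material)
    truth, nuisance = sample_concentrations(model, animals, manifest,
                                            seed + 1, panel)
    spectra = render_cohort(truth, panel, acq,
                            None if noiseless else nuisance, seed + 2,
                            noiseless=noiseless)
    return animals, truth, nuisance, spectra


def preprocess_all(spectra, material, panel, acq, excise=False):
    cfg = PreprocessConfig(material=material,
                           peak_windows=peak_mask_windows(panel, acq))
    return [preprocess_pipeline(s, cfg, excise=excise) for s in spectra]


@pytest.fixture(scope="session")
def plasma_cohort(acq, plasma_panel, plasma_model):
    """Small noisy plasma cohort with its quantified concentrations."""
    animals, truth, nuisance, spectra = make_cohort("plasma", 12, 7, acq=acq)
    proc = preprocess_all(spectra, "plasma", plasma_panel, acq)
    table = quantify_cohort(proc, plasma_panel, acq.tsp_conc, acq)
    return dict(animals=animals, truth=truth, nuisance=nuisance,
                spectra=spectra, processed=proc, table=table)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
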
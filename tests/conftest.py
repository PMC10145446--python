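import warnings

import pytest

from abzpbpk import (IonizationSpec, SolubilityParams, TransferConfig, WeibullPSD,
                     simulate_subject, simulate_transfer)
from abzpbpk.config import albendazole_default

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        module=r"scipy\.integrate\._ivp.*")


@pytest.fixture(scope="session")
def abz():
    """The shipped albendazole model configuration."""
    return albendazole_default()


@pytest.fixture(scope="session")
def abz_ion():
    return IonizationSpec(pka_acid=10.26, pka_base=2.8, species_type="ampholyte")


@pytest.fixture(scope="session")
def abz_sol():
    return SolubilityParams(S0=0.012, logKmw_neutral=2.924, logKmw_ion=5.423)


@pytest.fixture(scope="session")
def abz_psd():
    return WeibullPSD(alpha=1.014, beta=8.732)


@pytest.fixture(scope="session")
def transfer_400(abz):
    """The packaged 400 mg immediate-precipitation transfer simulation."""
    cfg = TransferConfig(dose_mg=400.0, psd=abz.formulation.psd,
                         release_rate_per_h=abz.formulation.release_rate_per_h)
    return simulate_transfer(cfg, abz.solubility, abz.ion, abz.dlm, abz.precip)


@pytest.fixture(scope="session")
def mean_subject(abz):
    """Mean-subject (70 kg) coupled GI + systemic simulation at 400 mg."""
    return simulate_subject(400.0, abz.physiology, abz.solubility, abz.ion,
                            abz.formulation, abz.dlm, abz.precip, abz.absorb,
                            abz.parent, abz.metabolite, body_weight_kg=70.0,
                            options=abz.options)
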
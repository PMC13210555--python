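import numpy as np
import pytest

from depotkit.iv_model import MacroModel
from depotkit.deconvolution import build_uir
from depotkit.pkdata_io import DoseEvent, PKDataset, PKSample


@pytest.fixture(scope="session")
def isl_model() -> MacroModel:
    """Biexponential disposition truth used across modules (islatravir-like)."""
    return MacroModel(coefficients=[5275.9, 6.3], exponents=[0.5, 0.1])


@pytest.fixture(scope="session")
def isl_uir(isl_model):
    return build_uir(isl_model, dose=1.5e7)  # 5 mg/kg x 3 kg in ng


@pytest.fixture()
def tiny_dataset() -> PKDataset:
    """One IV subject, three samples, one of them BLQ."""
    return PKDataset(
        samples=[
            PKSample("r1", "BIC", "IV", 0.5, 850.0, False, 1.0),
            PKSample("r1", "BIC", "IV", 6.0, 120.0, False, 1.0),
            PKSample("r1", "BIC", "IV", 30.0, None, True, 1.0),
        ],
        doses=[DoseEvent("r1", "BIC", "IV", amount=2.25e6)],
    )


def monoexp_dataset(lam=0.1, c0=100.0, times=(1.0, 5.0, 10.0, 20.0, 30.0)) -> PKDataset:
    samples = [
        PKSample("s1", "X", "IV", t, c0 * float(np.exp(-lam * t)), False, 1e-6)
        for t in times
    ]
    return PKDataset(samples=samples, doses=[DoseEvent("s1", "X", "IV", amount=1.0e6)])
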
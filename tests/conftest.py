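import warnings

import numpy as np
import pytest

from odeseq.basis import FourierBasis
from odeseq.coverage import ExpressionCurve


@pytest.fixture(scope="session")
def basis11():
    return FourierBasis(n_basis=11)


@pytest.fixture(scope="session")
def basis21():
    return FourierBasis(n_basis=21)


@pytest.fixture
def make_curve():
    def _make(y, t=None, sample_id="s0", gene_id="g", group=None):
        y = np.asarray(y, dtype=float)
        if t is None:
            t = np.linspace(0.0, 100.0, y.size)
        return ExpressionCurve(gene_id=gene_id, sample_id=sample_id, t=t, y=y, group=group)

    return _make


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # iteration-budget warnings are expected in stress tests; keep output clean
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        yield
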
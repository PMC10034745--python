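import numpy as np
import pytest

from mshdx import LabelingConditions, PeptideSpec, UptakeSeries
from mshdx.simulate import PRINTED_SCHEDULE


@pytest.fixture
def conditions():
    """Peptide-mixture labeling conditions (pD_read 7.06, 23 C, ~95% D2O)."""
    return LabelingConditions(pD_read=7.06, temperature=296.15, d2o_fraction=0.95)


@pytest.fixture
def bradykinin():
    return PeptideSpec("RPPGFSPFR", is_free_peptide=True)


@pytest.fixture
def schedule():
    return np.array(PRINTED_SCHEDULE)


def make_series(peptide, times, curve, noise_sd=0.0, n_rep=1, seed=0, **kw):
    """Build an UptakeSeries around a noise-free curve."""
    rng = np.random.default_rng(seed)
    u = np.asarray(curve, dtype=float)[:, None] + noise_sd * rng.standard_normal(
        (len(times), n_rep)
    )
    return UptakeSeries(peptide, times, np.clip(u, 0.0, None), **kw)
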
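import numpy as np
import pandas as pd
import pytest

from rcsbuffer.csp import TitrationSeries
from rcsbuffer.equilibrium import BindingSystem


@pytest.fixture
def physiological_system() -> BindingSystem:
    """The measured constants and estimated periplasmic pools, in µM."""
    return BindingSystem(r_total=15.0, a_total=1000.0, i_total=1.0, kd_a=125.0, kd_i=0.0016)


def make_peaks(ids, names=None, h=None, n=None) -> pd.DataFrame:
    ids = np.asarray(ids)
    return pd.DataFrame(
        {
            "residue_id": ids,
            "residue_name": names if names is not None else ["A"] * len(ids),
            "shift_h_ppm": h if h is not None else np.full(len(ids), 8.0),
            "shift_n_ppm": n if n is not None else np.full(len(ids), 115.0),
        }
    )


@pytest.fixture
def two_point_series() -> TitrationSeries:
    """Minimal titration: reference plus one saturating point, two residues shifted."""
    ref = make_peaks([1, 2, 3], h=[8.0, 8.2, 8.4], n=[110.0, 115.0, 120.0])
    sat = make_peaks([1, 2, 3], h=[8.03, 8.2, 8.4], n=[110.10, 115.0, 120.0])
    return TitrationSeries(protein_conc_uM=50.0, points={0.0: ref, 10.0: sat})
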
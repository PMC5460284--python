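import numpy as np
import pandas as pd
import pytest

from amtpipe import simulate


def make_config(**kwargs) -> simulate.SimulationConfig:
    base = dict(n_proteins=20, n_extra_genes=0, seed=11)
    base.update(kwargs)
    return simulate.SimulationConfig(**base)


@pytest.fixture
def small_config():
    return make_config()


@pytest.fixture
def noiseless_config():
    """Zero measurement noise, full detection, every feature identified."""
    return make_config(
        mass_error_ppm_sd=0.0,
        net_error_sd=0.0,
        intensity_noise_sd=0.0,
        detection_rate=1.0,
        id_rate=1.0,
        low_score_rate=0.0,
    )


def features_frame(masses, scans, intensities=None, run_id="r1", **extra):
    """Minimal hand-built ion-feature table."""
    n = len(masses)
    if intensities is None:
        intensities = [1.0] * n
    df = pd.DataFrame(
        {
            "run_id": run_id,
            "scan": scans,
            "charge": [2] * n,
            "monoiso_mass_da": masses,
            "intensity": intensities,
            "peptide_seq": extra.get("peptide_seq", [None] * n),
            "id_score": extra.get("id_score", [np.nan] * n),
            "protein_ids": extra.get("protein_ids", [()] * n),
        }
    )
    return df
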
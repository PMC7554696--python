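import numpy as np
import pytest

from dnaintercal import synthetic as syn


@pytest.fixture(scope="session")
def preset():
    return syn.load_preset("paper_like")


@pytest.fixture(scope="session")
def ideal_uvvis_series():
    """Noiseless idealized absorbance titration at the published conditions."""
    return syn.gen_uvvis_titration(
        K_A=1.10e6,
        eps_f=11500.0,
        eps_b=6000.0,
        ligand_total=1.8e-5,
        dna_concs=np.linspace(1.9e-7, 1.9e-6, 10),
    )


@pytest.fixture(scope="session")
def static_quench_series():
    """Noiseless 1:1 static-quenching titration, K_A = 1e7 1/M."""
    return syn.gen_fluor_titration(
        K_A=1.0e7, F0=1000.0, q_concs=np.linspace(5e-9, 7.5e-8, 15)
    )


@pytest.fixture(scope="session")
def two_blob_ensemble():
    """1000 frames from two well-separated conformer blobs (85/15)."""
    rng = np.random.default_rng(0)
    base = rng.normal(0.0, 0.3, (12, 3))
    shifted = base + np.array([1.0, 0.0, 0.0])   # coordinate RMSD exactly 1.0 nm
    ensemble, labels = syn.gen_conformer_ensemble(
        n_frames=1000,
        blueprint=[
            {"center_coords": base, "population_fraction": 0.85, "jitter_sd": 0.02},
            {"center_coords": shifted, "population_fraction": 0.15, "jitter_sd": 0.02},
        ],
        seed=1,
    )
    return ensemble, labels
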
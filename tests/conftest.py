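"""Shared fixtures: small carbanion inputs, mock backend runs, toy models."""

import numpy as np
import pandas as pd
import pytest

from co2screen.modeling import MLRModel
from co2screen.pipeline import PipelineConfig
from co2screen.qm_interface import MockBackend, run_backend
from co2screen.structures import embed_ensemble, parse_smiles_input

# a small batch covering passes, fails and a pattern reject
SMILES_BATCH = """\
[CH-]1C=Cc2ccccc21 indenide
[CH-](C#N)C#N malononitrile_anion
CC(=O)[CH-]C(C)=O acac_anion
[CH3-] methide
O=C1OC2=CC=CC=C2[CH-]1 benzofuranone
"""


@pytest.fixture(scope="session")
def smi_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("inputs") / "batch.smi"
    path.write_text(SMILES_BATCH)
    return path


@pytest.fixture(scope="session")
def parsed_batch(smi_file):
    return parse_smiles_input(smi_file)


@pytest.fixture(scope="session")
def indenide(parsed_batch):
    return next(r for r in parsed_batch.records if r.id == "indenide")


@pytest.fixture(scope="session")
def indenide_ensemble(indenide):
    return embed_ensemble(indenide, n_confs=10, seed=7)


@pytest.fixture(scope="session")
def mock_results(parsed_batch):
    """Affinity-level mock results for every conformer of every record."""
    backend = MockBackend()
    cfg = PipelineConfig(input="unused")
    ensembles, results = {}, {}
    for record in parsed_batch.records:
        ens = embed_ensemble(record, n_confs=10, seed=7)
        ensembles[record.id] = ens
        results[record.id] = [
            run_backend(
                c,
                record.elements,
                cfg.settings(2),
                backend,
                require=("single_point", "thermochemistry", "hirshfeld"),
            )
            for c in ens.conformers
        ]
    return ensembles, results


@pytest.fixture
def toy_model():
    """Hand-built affinity model over the default boltz feature triple."""
    return MLRModel(
        feature_names=[
            "epsilon_homo_boltz",
            "site_dipole_boltz",
            "buried_b1_boltz",
        ],
        coefficients=np.array([1.0, 0.5, 0.3]),
        intercept=1.0,
        scaler=[(-0.15, 0.01), (0.1, 0.05), (1.7, 0.2)],
    )


@pytest.fixture
def linear_table():
    """Noiseless y = 2 x1 - x2 + 0.5 x3 over 20 rows, plus a decoy."""
    rng = np.random.default_rng(11)
    x = rng.normal(size=(20, 4))
    df = pd.DataFrame(x, columns=["x1", "x2", "x3", "decoy"])
    df["co2a"] = 2 * df.x1 - df.x2 + 0.5 * df.x3
    df.index = [f"m{i}" for i in range(20)]
    return df
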
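from __future__ import annotations

import numpy as np
import pytest

import dcrisk as d


def random_cds(rng: np.random.Generator, length: int) -> str:
    """Random A/C/G/T string (no CDS structure constraints)."""
    return "".join(rng.choice(list("TCAG"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_ref() -> d.ReferenceCDS:
    return d.ReferenceCDS(id="tiny", sequence="ATGGCCAAATAG")


@pytest.fixture(scope="session")
def small_sim_config() -> d.SimulationConfig:
    """A scaled-down simulation for unit tests (the default-scale study
    conditions are exercised in the acceptance suite)."""
    return d.SimulationConfig(
        reference_length=1500,
        counts={"Pathogenic": 40, "Benign": 20, "Benignlikely": 20,
                "Pathogeniclikely": 15, "Uncertain": 15},
        n_intron_rows=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_fixture(small_sim_config, tmp_path_factory):
    """Reference, parsed records, reconstructed variant CDS and ground
    truth for the scaled-down simulation."""
    out = tmp_path_factory.mktemp("fixture")
    ref = d.generate_reference(small_sim_config)
    table, truth = d.generate_variant_table(ref, small_sim_config)
    path = out / "variants.tsv"
    table.to_csv(path, sep="\t", index=False)
    records = d.parse_variant_table(path)
    variants = d.reconstruct_all(ref, records)
    return {"config": small_sim_config, "ref": ref, "table": table,
            "table_path": path, "truth": truth, "records": records,
            "variants": variants}


@pytest.fixture(scope="session")
def small_training_data(small_fixture):
    """Balanced DCR tensors + labels from the scaled-down simulation."""
    variants = [v for v in small_fixture["variants"]
                if v.record.significance in
                ("Pathogenic", "Benign", "Benignlikely")]
    X = np.stack([d.count_dcr(v.sequence).values for v in variants])
    y = np.array([1 if v.record.significance == "Pathogenic" else 0
                  for v in variants])
    return X, y, variants


@pytest.fixture(scope="session")
def small_trained_model(small_training_data):
    """A quickly trained model (reduced epochs) for prediction tests."""
    X, y, _ = small_training_data
    cfg = d.ModelConfig(seed=7, epochs=25)
    res = d.DCRClassifier(X, y, cfg).fit()
    return res
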
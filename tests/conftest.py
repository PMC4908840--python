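import numpy as np
import pandas as pd
import pytest

from methlink import SimulationConfig, simulate_study


@pytest.fixture
def toy_annotation_csv(tmp_path):
    """Three probe-gene rows with custom column names."""
    path = tmp_path / "probes.csv"
    path.write_text(
        "probe,chr,position,symbol,dist,snp\n"
        "cg001,chr1,1000,GENEA,-120,FALSE\n"
        "cg002,chr1,1500,GENEA,380,TRUE\n"
        "cg003,chr2,9000,GENEB,1500,FALSE\n"
    )
    return path


@pytest.fixture(scope="session")
def small_config():
    """Compact study: 8 synthetic genes, strong planted effects."""
    return SimulationConfig(
        genes=tuple(f"GENE{i}" for i in range(8)),
        disease_effect=0.5,
        coupled_fraction=1.0,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, seed=11)


@pytest.fixture(scope="session")
def probe_sets_for(small_study):
    """Per-gene TSS-window probe id sets of the small study."""
    from methlink import select_tss1500_probes

    probes = small_study.truth.probe_records()
    genes = small_study.truth.genes["gene"]
    return {g: ids for g in genes if (ids := select_tss1500_probes(probes, g))}


def make_beta(logits: np.ndarray, probe_ids, sample_ids) -> pd.DataFrame:
    """Beta matrix from a logit array (test helper)."""
    beta = 1.0 / (1.0 + np.exp(-np.asarray(logits, dtype=float)))
    return pd.DataFrame(beta, index=list(probe_ids), columns=list(sample_ids))
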
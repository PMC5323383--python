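import numpy as np
import pytest

from mutscape import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mock_ligand():
    return syn.make_mock_ligand(12, 12.0)


@pytest.fixture
def small_ensemble():
    """A 400-pose planted ensemble: enough to exercise every group."""
    cfg = syn.SyntheticEnsembleConfig(n_poses=400, seed=7)
    return syn.sample_ensemble(cfg)


@pytest.fixture
def clustal_file(tmp_path):
    text = (
        "CLUSTAL W (1.83) multiple sequence alignment\n"
        "\n"
        "s1   MA-KV\n"
        "s2   MAGKV\n"
        "s3   MAGRV\n"
        "s4   MAGRV\n"
    )
    path = tmp_path / "aln.clustal"
    path.write_text(text)
    groups = tmp_path / "groups.tsv"
    groups.write_text("s1\t1\ns2\t1\ns3\t2\ns4\t2\n")
    return path, groups
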
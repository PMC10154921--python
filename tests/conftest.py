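import numpy as np
import pytest

from traitnet import TraitMatrix, TraitModality


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trait_matrix(scores, categories, taxa=None, traits=None, binary=None):
    """Build a TraitMatrix from a score array and per-column categories."""
    scores = np.asarray(scores, dtype=float)
    n_taxa, n_mod = scores.shape
    taxa = taxa or [f"t{i}" for i in range(n_taxa)]
    modalities = [
        TraitModality(
            id=f"m{j}", trait=(traits[j] if traits else f"m{j}"), category=c
        )
        for j, c in enumerate(categories)
    ]
    if binary is None:
        binary = bool(np.isin(scores, (0.0, 1.0)).all())
    return TraitMatrix(taxa=taxa, modalities=modalities, scores=scores, binary=binary)


@pytest.fixture
def small_traits():
    """4 taxa x 5 modalities, one modality per category, fully binary."""
    scores = [
        [1, 1, 0, 1, 0],
        [1, 0, 1, 1, 0],
        [1, 1, 0, 0, 1],
        [0, 1, 1, 1, 0],
    ]
    return make_trait_matrix(scores, ["REG", "REC_e", "REC_i", "RES_e", "RES_i"])


TRAIT_CSV = """taxon,m_a,m_b,m_c,m_d
#category,REG,REC_e,RES_e,RES_i
#trait,feeding,recovery,resistance,resistance
snail,1,0,1,0
clam,1,1,0,0
worm,0,1,1,1
"""


@pytest.fixture
def trait_csv(tmp_path):
    p = tmp_path / "traits.csv"
    p.write_text(TRAIT_CSV)
    return p
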
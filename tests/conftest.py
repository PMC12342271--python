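import numpy as np
import pytest

from comutnet.cohort import BinaryCohortMatrix, MutationKey, SampleMeta, parse_key


def matrix_from_carriers(carriers: dict[str, list[str]], samples: list[str]) -> BinaryCohortMatrix:
    """Build a presence matrix from {key text: [sample ids]}."""
    keys = sorted(parse_key(k) for k in carriers)
    cells = np.zeros((len(samples), len(keys)), dtype=np.uint8)
    sidx = {s: i for i, s in enumerate(samples)}
    for j, key in enumerate(keys):
        for sid in carriers[key.render()]:
            cells[sidx[sid], j] = 1
    return BinaryCohortMatrix(samples=list(samples), mutations=keys, cells=cells)


def metadata_for(samples, tissue="breast", metastatic=()):
    return {
        s: SampleMeta(
            sample_id=s,
            tissue=tissue[s] if isinstance(tissue, dict) else tissue,
            sample_type="metastatic" if s in set(metastatic) else "primary",
        )
        for s in samples
    }


@pytest.fixture
def toy_matrix():
    samples = [f"s{i}" for i in range(8)]
    return matrix_from_carriers(
        {
            "KRAS:G12D": ["s0", "s1", "s2", "s3"],
            "TP53:R175H": ["s0", "s1", "s2", "s4"],
            "PIK3CA:E545K": ["s5", "s6"],
            "PIK3CA:H1047R": ["s0", "s7"],
        },
        samples,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
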
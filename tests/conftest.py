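import numpy as np
import pytest

from starscan.genotype_io import GenotypeMatrix, PopulationAssignment


@pytest.fixture
def small_matrix():
    """8 segregating sites, 2 ref + 2 tgt + 1 src samples, one chromosome."""
    rng = np.random.default_rng(42)
    n_sites, samples = 8, ["ref_0", "ref_1", "tgt_0", "tgt_1", "src_0"]
    pos = np.sort(rng.choice(np.arange(1, 10_001), size=n_sites,
                             replace=False))
    G = rng.integers(0, 3, size=(n_sites, len(samples))).astype(np.int8)
    gm = GenotypeMatrix(["1"] * n_sites, pos, ["A"] * n_sites,
                        ["G"] * n_sites, [True] * n_sites, samples, G)
    assignment = PopulationAssignment(["ref_0", "ref_1"], ["tgt_0", "tgt_1"],
                                      {"src": ["src_0"]})
    return gm, assignment


@pytest.fixture
def popmap_file(tmp_path):
    path = tmp_path / "popmap.tsv"
    lines = [f"ref_{i}\tAFR" for i in range(10)] + \
            [f"tgt_{i}\tPAP" for i in range(5)] + \
            ["src_0\tNEA"]
    path.write_text("\n".join(lines) + "\n")
    return path
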
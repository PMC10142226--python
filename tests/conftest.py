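import numpy as np
import pandas as pd
import pytest

from sludgecast.preprocess import encode_binary, impute_2nn, normalize_1_100, relative_abundance
from sludgecast.synthetic import generate_env_table, generate_neutral_counts, generate_tree


@pytest.fixture(scope="session")
def env_small():
    """10 samples x 8 factors (6 numeric + 2 binary), no missing cells."""
    return generate_env_table(10, n_numeric=6, n_binary=2, missing_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def env_normalized():
    env = generate_env_table(60, n_numeric=10, n_binary=2, missing_rate=0.05, seed=5)
    return normalize_1_100(impute_2nn(encode_binary(env)))


@pytest.fixture(scope="session")
def neutral_counts():
    """Modest neutral community: 60 samples x 80 taxa at depth 500."""
    counts, truth = generate_neutral_counts(60, 80, m=0.2, reads_per_sample=500, seed=3)
    return counts, truth


@pytest.fixture(scope="session")
def neutral_abund(neutral_counts):
    counts, _ = neutral_counts
    return relative_abundance(counts)


@pytest.fixture(scope="session")
def small_tree():
    return generate_tree([f"ASV{i:05d}" for i in range(12)], seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def star_tree(n_leaves: int, branch_length: float = 1.0):
    """Effectively a star: leaves hang off two zero-length stems under the
    root (a bifurcating root keeps phylogenetic validators happy while every
    leaf still sits at ``branch_length`` from the root)."""
    from skbio import TreeNode

    root = TreeNode()
    stems = [TreeNode(length=0.0), TreeNode(length=0.0)]
    root.extend(stems)
    for i in range(n_leaves):
        stems[i % 2].append(TreeNode(name=f"L{i}", length=branch_length))
    return root


def abund_frame(rows, taxa=None, samples=None) -> pd.DataFrame:
    arr = np.asarray(rows, dtype=float)
    taxa = taxa or [f"t{j}" for j in range(arr.shape[1])]
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=samples, columns=taxa)
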
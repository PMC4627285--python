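import numpy as np
import pytest

from synerscan import SimConfig, generate_design, generate_expression


@pytest.fixture
def small_design():
    return generate_design(3, include_inhibitor_arm=True)


@pytest.fixture
def zero_noise_data():
    """200-gene zero-noise factorial dataset with every planted class."""
    config = SimConfig(n_genes=200, n_replicates=2, noise_sd=0.0, seed=11)
    design = generate_design(config.n_replicates, include_inhibitor_arm=True)
    matrix, truth = generate_expression(config, design)
    return config, design, matrix, truth


@pytest.fixture
def noisy_data():
    """Default-condition dataset: 2000 genes, 5% synergistic, noise 0.25."""
    config = SimConfig(seed=3)
    design = generate_design(config.n_replicates, include_inhibitor_arm=True)
    matrix, truth = generate_expression(config, design)
    return config, design, matrix, truth


def naive_average_linkage(D, tie_key):
    """O(n^3) reference agglomerator recomputing cluster-pair averages each step.

    ``D`` is the precomputed leaf-level distance matrix; ``tie_key(leaves_a,
    leaves_b)`` must order candidate pairs the same way the implementation
    under test does. Returns a list of (left_node, right_node, height) with
    the same node numbering convention (leaves 0..n-1, then merge order).
    """
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}  # node id -> leaf list
    merges = []
    next_node = n
    for _ in range(n - 1):
        best = None
        best_d = None
        best_key = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                la, lb = clusters[a], clusters[b]
                d = np.mean([D[i, j] for i in la for j in lb])
                key = tie_key(la, lb)
                if best_d is None or d < best_d or (d == best_d and key < best_key):
                    best_d, best_key, best = d, key, (a, b)
        a, b = best
        # left child: smaller min leaf index
        if min(clusters[a]) > min(clusters[b]):
            a, b = b, a
        merges.append((a, b, float(best_d)))
        clusters[next_node] = clusters.pop(a) + clusters.pop(b)
        next_node += 1
    return merges


def lexicographic_tie_key(leaves_a, leaves_b):
    a, b = sorted((min(leaves_a), min(leaves_b)))
    return (a, b)
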
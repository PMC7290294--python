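"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from omegascan import (
    CleaningPolicy,
    CodonModelSpec,
    ModelFamily,
    STANDARD_CODE,
    SimulationConfig,
    clean_alignment,
    random_tree,
    simulate_alignment,
)
from omegascan.codon_model import CodonFrequencies, FrequencyScheme, build_rate_matrix
from omegascan.genetics import MISSING
from omegascan.trees import Node, PhyloTree


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture(scope="session")
def uniform_freqs():
    return CodonFrequencies(FrequencyScheme.CF0, np.full(61, 1.0 / 61.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def small_sim():
    """One 8-taxon, 250-codon simulation with a relaxed foreground clade."""
    rng = np.random.default_rng(3)
    tree = random_tree(8, rng)
    fg = tree.leaves[:2]
    tree.set_categories(foreground=fg, category=1, clade_inclusive=True, reset=True)
    cfg = SimulationConfig(
        tree=tree, omega_by_category={0: 0.4, 1: 2.0}, n_codons=250, seed=2
    )
    bundle = simulate_alignment(cfg)
    codon_aln, _ = clean_alignment(bundle.alignment, STANDARD_CODE, CleaningPolicy())
    return {"tree": tree, "foreground": fg, "bundle": bundle, "codon_aln": codon_aln}


def brute_force_log_likelihood(
    encoded: np.ndarray,
    taxa: list[str],
    tree: PhyloTree,
    freqs: CodonFrequencies,
    kappa: float,
    omega_by_category: dict[int, float],
    code,
) -> float:
    """Likelihood by explicit summation over all internal-node states.

    Enumerates every assignment of the 61 codon states to internal nodes
    and sums products of transition probabilities — exponential in the
    number of internal nodes, usable only on tiny trees, and entirely
    independent of the pruning implementation.
    """
    row = {t: i for i, t in enumerate(taxa)}
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    P = {}
    for n in nodes:
        if n.parent is not None:
            Q = build_rate_matrix(freqs, kappa, omega_by_category[n.category], code)
            P[id(n)] = Q.transition_probabilities(n.length)
    n_sites = encoded.shape[1]
    total = 0.0
    for site in range(n_sites):
        site_l = 0.0
        for assignment in itertools.product(range(61), repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assignment)}
            for n in nodes:
                if n.is_leaf:
                    state[id(n)] = encoded[row[n.name], site]
            prob = freqs.pi[state[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                s_child = state[id(n)]
                if s_child == MISSING:
                    continue  # marginalized: leaf contributes sum_j P[i,j] = 1
                prob *= P[id(n)][state[id(n.parent)], s_child]
            site_l += prob
        total += np.log(site_l)
    return float(total)
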
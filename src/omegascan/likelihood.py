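"""Felsenstein pruning likelihood for codon models on trees.

Site patterns are compressed before pruning; conditional likelihoods are
rescaled per pattern to avoid underflow, and MISSING states contribute
all-ones partial vectors.  Branch-specific omegas are supported by giving
each branch its own rate matrix; rate matrices are cached per (kappa,
omega) so a branch-model fit builds one matrix per omega category per
objective evaluation.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .codon_model import CodonFrequencies, CodonRateMatrix, build_rate_matrix
from .genetics import MISSING, GeneticCode
from .trees import Node, PhyloTree


class NumericalLikelihoodError(ArithmeticError):
    """A site pattern received zero or non-finite likelihood."""


def compress_patterns(encoded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse alignment columns into unique site patterns with weights."""
    patterns, counts = np.unique(encoded, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class PruningEngine:
    """Reusable pruning machinery bound to one alignment + tree.

    The tree is deep-copied at construction; branch lengths and omegas are
    supplied per call so an optimizer can reuse the engine across
    objective evaluations.
    """

    def __init__(
        self,
        encoded: np.ndarray,
        taxa: Sequence[str],
        tree: PhyloTree,
        code: GeneticCode,
    ) -> None:
        leaves = set(tree.leaves)
        if leaves != set(taxa):
            raise ValueError(
                f"tree leaves and alignment taxa differ: only_tree="
                f"{sorted(leaves - set(taxa))}, only_aln={sorted(set(taxa) - leaves)}"
            )
        self.tree = tree.copy()
        self.code = code
        self.patterns, self.weights = compress_patterns(encoded)
        self.n_patterns = self.patterns.shape[1]
        self.n_sites = int(self.weights.sum())
        row = {t: i for i, t in enumerate(taxa)}
        self.postorder: list[Node] = list(self.tree.postorder())
        self.branches: list[Node] = [n for n in self.postorder if n.parent is not None]
        self._leaf_partials: dict[int, np.ndarray] = {}
        for node in self.postorder:
            if node.is_leaf:
                obs = self.patterns[row[node.name]]
                part = np.zeros((self.n_patterns, 61))
                known = obs != MISSING
                part[known, obs[known]] = 1.0
                part[~known, :] = 1.0
                self._leaf_partials[id(node)] = part
        self._qcache: dict[tuple, CodonRateMatrix] = {}

    def rate_matrix(self, freqs: CodonFrequencies, kappa: float, omega: float) -> CodonRateMatrix:
        key = (id(freqs), round(float(kappa), 12), round(float(omega), 12))
        Q = self._qcache.get(key)
        if Q is None:
            if len(self._qcache) > 256:
                self._qcache.clear()
            Q = build_rate_matrix(freqs, kappa, omega, self.code)
            self._qcache[key] = Q
        return Q

    def site_log_likelihoods(
        self,
        freqs: CodonFrequencies,
        kappa: float,
        omega_of_branch: Callable[[Node], float],
        lengths: dict[int, float] | None = None,
    ) -> np.ndarray:
        """Per-pattern log-likelihood under branch-specific omegas.

        ``lengths`` optionally overrides branch lengths, keyed by id(node);
        otherwise each node's own ``length`` attribute is used.
        """
        partials: dict[int, np.ndarray] = {}
        scale = np.zeros(self.n_patterns)
        for node in self.postorder:
            if node.is_leaf:
                part = self._leaf_partials[id(node)]
            else:
                part = np.ones((self.n_patterns, 61))
                for child in node.children:
                    t = lengths[id(child)] if lengths is not None else child.length
                    if t is None:
                        raise ValueError("branch length unset during likelihood evaluation")
                    Q = self.rate_matrix(freqs, kappa, omega_of_branch(child))
                    P = Q.transition_probabilities(t)
                    part = part * (partials.pop(id(child)) @ P.T)
                top = part.max(axis=1)
                low = top < 1e-200
                if low.any():
                    safe = np.where(top > 0, top, 1.0)
                    part = part / safe[:, None]
                    scale = scale + np.log(safe)
            partials[id(node)] = part
        root_part = partials[id(self.postorder[-1])]
        site_l = root_part @ freqs.pi
        if (site_l <= 0).any():
            bad = int(np.argmax(site_l <= 0))
            raise NumericalLikelihoodError(f"zero likelihood at site pattern {bad}")
        return np.log(site_l) + scale

    def log_likelihood(
        self,
        freqs: CodonFrequencies,
        kappa: float,
        omega_of_branch: Callable[[Node], float],
        lengths: dict[int, float] | None = None,
    ) -> float:
        site_ll = self.site_log_likelihoods(freqs, kappa, omega_of_branch, lengths)
        return float(self.weights @ site_ll)


def log_likelihood(
    encoded: np.ndarray,
    taxa: Sequence[str],
    tree: PhyloTree,
    freqs: CodonFrequencies,
    kappa: float,
    omega: float | dict[int, float],
    code: GeneticCode,
) -> float:
    """One-shot pruning log-likelihood.

    ``omega`` is either a single ratio applied to every branch or a mapping
    from branch category to ratio.
    """
    engine = PruningEngine(encoded, taxa, tree, code)
    if isinstance(omega, dict):
        fn = lambda node: omega[node.category]
    else:
        fn = lambda node: float(omega)
    return engine.log_likelihood(freqs, kappa, fn)
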
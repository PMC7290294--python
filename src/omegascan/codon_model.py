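"""The 61-state codon substitution process (GY94 parameterization).

Equilibrium codon frequencies come in the four schemes used by codeml:
equal (CF0, codeml Fequal), from pooled nucleotide frequencies (CF1,
F1x4), from position-specific nucleotide frequencies (CF2, F3x4), and
empirical codon proportions (CF3, F61).  The instantaneous rate matrix
follows Goldman & Yang: a single-nucleotide change i->j gets rate
``pi_j * kappa^[transition] * omega^[nonsynonymous]``, multi-nucleotide
changes get rate 0, and the matrix is rescaled so that branch lengths are
expected substitutions per codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .genetics import MISSING, NUCLEOTIDES, GeneticCode, is_transition


class FrequencyScheme(str, Enum):
    CF0 = "CF0"  # equal
    CF1 = "CF1"  # F1x4: pooled nucleotide frequencies
    CF2 = "CF2"  # F3x4: per-codon-position nucleotide frequencies
    CF3 = "CF3"  # F61: empirical codon proportions

    @property
    def n_free_params(self) -> int:
        return {"CF0": 0, "CF1": 3, "CF2": 9, "CF3": 60}[self.value]


class DegenerateDataError(ValueError):
    """Alignment carries no usable codon data."""


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium distribution over the 61 sense codons."""

    scheme: FrequencyScheme
    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (61,):
            raise ValueError("pi must have 61 entries")
        if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be non-negative and sum to 1")
        object.__setattr__(self, "pi", pi)

    @property
    def n_free_params(self) -> int:
        return self.scheme.n_free_params


def estimate_frequencies(
    encoded: np.ndarray,
    code: GeneticCode,
    scheme: FrequencyScheme | str,
    pseudocount: float = 1.0 / 61.0,
) -> CodonFrequencies:
    """Estimate equilibrium codon frequencies from an encoded alignment.

    Parameters
    ----------
    encoded:
        (n_taxa, n_sites) matrix of sense-codon indices with MISSING for
        gapped/ambiguous triplets, as produced by ``encode_codons``.
    scheme:
        One of CF0..CF3.
    pseudocount:
        Added to unobserved sense codons under CF3 so the chain stays
        irreducible; set to 0 for raw empirical proportions.
    """
    scheme = FrequencyScheme(scheme)
    if hasattr(encoded, "codon_rows"):  # accept a CodonAlignment directly
        from .alignment import encode_codons

        encoded = encode_codons(encoded, code)
    observed = encoded[encoded != MISSING]
    if scheme is not FrequencyScheme.CF0 and observed.size == 0:
        raise DegenerateDataError("no non-missing codons to estimate frequencies from")

    if scheme is FrequencyScheme.CF0:
        pi = np.full(61, 1.0 / 61.0)
        return CodonFrequencies(scheme, pi)

    if scheme is FrequencyScheme.CF3:
        counts = np.bincount(observed, minlength=61).astype(float)
        counts[counts == 0] += pseudocount
        return CodonFrequencies(scheme, counts / counts.sum())

    # nucleotide-frequency schemes: count bases over observed codons
    nt_index = {b: k for k, b in enumerate(NUCLEOTIDES)}
    codon_nt = np.array(
        [[nt_index[b] for b in codon] for codon in code.sense_codons], dtype=int
    )  # (61, 3)
    counts = np.zeros((3, 4))
    state_counts = np.bincount(observed, minlength=61).astype(float)
    for pos in range(3):
        for s in range(61):
            counts[pos, codon_nt[s, pos]] += state_counts[s]

    if scheme is FrequencyScheme.CF1:
        f = counts.sum(axis=0)
        f = f / f.sum()
        pi = f[codon_nt[:, 0]] * f[codon_nt[:, 1]] * f[codon_nt[:, 2]]
    else:  # CF2
        f = counts / counts.sum(axis=1, keepdims=True)
        pi = f[0, codon_nt[:, 0]] * f[1, codon_nt[:, 1]] * f[2, codon_nt[:, 2]]

    total = pi.sum()
    if total <= 0:
        raise DegenerateDataError("nucleotide frequencies put zero mass on sense codons")
    return CodonFrequencies(scheme, pi / total)


@dataclass(frozen=True)
class CodonRateMatrix:
    """Scaled GY94 instantaneous rate matrix with its eigendecomposition.

    The decomposition uses the similarity transform ``S = D^{1/2} Q D^{-1/2}``
    with ``D = diag(pi)``; S is symmetric for a time-reversible Q, so
    transition probabilities are computed with a single ``eigh`` reused for
    every branch length.
    """

    Q: np.ndarray
    pi: np.ndarray
    kappa: float
    omega: float
    scaled: bool = True
    _eig: tuple = field(default=None, repr=False, compare=False)

    def transition_probabilities(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clamped at 0."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        evals, evecs, d_sqrt, d_isqrt = self._eig
        P = (d_isqrt[:, None] * evecs) @ (
            np.exp(evals * t)[:, None] * (evecs.T * d_sqrt[None, :])
        )
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# cached structural tables, keyed by genetic code identity
_STRUCT_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _structure_tables(code: GeneticCode) -> tuple[np.ndarray, np.ndarray]:
    """(is_transition, is_nonsynonymous) boolean masks over single-step pairs.

    Entries are 0 where codons differ at zero or more than one position.
    """
    key = id(code)
    if key in _STRUCT_CACHE:
        return _STRUCT_CACHE[key]
    n = 61
    single = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    codons = code.sense_codons
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(codons[i], codons[j]) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            ts[i, j] = is_transition(*diffs[0])
            nonsyn[i, j] = not code.is_synonymous(i, j)
    _STRUCT_CACHE[key] = (single, ts, nonsyn)
    return _STRUCT_CACHE[key]


def build_rate_matrix(
    freqs: CodonFrequencies,
    kappa: float,
    omega: float,
    code: GeneticCode,
    scale: bool = True,
) -> CodonRateMatrix:
    """Construct the scaled GY94 rate matrix for given kappa and omega."""
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    single, ts, nonsyn = _structure_tables(code)
    pi = freqs.pi
    Q = np.where(single, pi[None, :], 0.0)
    Q = Q * np.where(ts, kappa, 1.0) * np.where(nonsyn, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mean_rate = -(pi * np.diag(Q)).sum()
        if mean_rate > 0:
            Q = Q / mean_rate
    # symmetric eigendecomposition in the pi-weighted inner product;
    # zero-frequency states (possible under CF1/CF3 without pseudocounts)
    # are isolated, so a tiny floor keeps the transform well defined
    safe_pi = np.maximum(pi, 1e-300)
    d_sqrt = np.sqrt(safe_pi)
    d_isqrt = 1.0 / d_sqrt
    S = d_sqrt[:, None] * Q * d_isqrt[None, :]
    S = 0.5 * (S + S.T)
    evals, evecs = np.linalg.eigh(S)
    return CodonRateMatrix(
        Q=Q, pi=pi, kappa=kappa, omega=omega, scaled=scale,
        _eig=(evals, evecs, d_sqrt, d_isqrt),
    )


def transition_probabilities(Q: CodonRateMatrix, t: float) -> np.ndarray:
    """Functional wrapper around :meth:`CodonRateMatrix.transition_probabilities`."""
    return Q.transition_probabilities(t)
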
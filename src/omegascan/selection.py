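"""Maximum-likelihood codon-model fitting and tests of relaxed selection.

Implements the model families used to diagnose relaxation of purifying
selection on a marker gene:

* ``one_ratio`` — a single omega shared by every branch (the null);
* ``branch`` — one omega per branch category (foreground vs background,
  or several foreground categories);
* ``free_ratio`` — an independent omega on every branch, used as an
  exploratory screen for elevated-omega lineages;
* ``branch_site_A`` / ``branch_site_A_null`` — the site-class mixture
  that tests for positive selection on foreground branches (alternative:
  omega2 >= 1 free; null: omega2 = 1).

Fits are bounded quasi-Newton optimizations on log-transformed kappa and
omega with jittered multi-restarts; omega estimates that hit the upper
bound are reported as 999, the conventional sentinel for categories with
no inferred synonymous change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .alignment import CodonAlignment, encode_codons
from .codon_model import CodonFrequencies, FrequencyScheme, estimate_frequencies
from .genetics import GeneticCode, STANDARD_CODE
from .likelihood import PruningEngine
from .trees import Node, PhyloTree

logger = logging.getLogger(__name__)

OMEGA_BOUNDS = (1e-4, 999.0)
KAPPA_BOUNDS = (1e-2, 100.0)
LENGTH_BOUNDS = (1e-7, 50.0)
#: Omega estimates at or beyond this are reported as the 999 sentinel.
OMEGA_CAP = OMEGA_BOUNDS[1]
#: Default free-ratio screening threshold for "elevated omega" branches.
SCREEN_THRESHOLD = 0.8


class ModelFamily(str, Enum):
    one_ratio = "one_ratio"
    branch = "branch"
    free_ratio = "free_ratio"
    branch_site_A = "branch_site_A"
    branch_site_A_null = "branch_site_A_null"


class ModelSpecError(ValueError):
    pass


class NestingError(ValueError):
    """LRT inputs are not a valid nested pair."""


@dataclass(frozen=True)
class CodonModelSpec:
    """What to fit: model family, frequency scheme, and optimizer policy."""

    family: ModelFamily = ModelFamily.one_ratio
    freq_scheme: FrequencyScheme = FrequencyScheme.CF0
    estimate_branch_lengths: bool = True
    n_restarts: int = 3
    omega_bounds: tuple[float, float] = OMEGA_BOUNDS
    kappa_bounds: tuple[float, float] = KAPPA_BOUNDS

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", ModelFamily(self.family))
        object.__setattr__(self, "freq_scheme", FrequencyScheme(self.freq_scheme))


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    spec: CodonModelSpec
    lnL: float
    kappa_hat: float
    omega_hat: dict  # category index (or branch clade-id) -> omega
    branch_lengths_hat: dict  # clade-id tuple -> length
    site_class_props: tuple[float, float] | None
    n_free_params: int
    converged: bool
    n_restarts_used: int
    flagged_branches: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_params - 2.0 * self.lnL

    def omega_report(self) -> dict:
        """Omega estimates with the 999 cap convention applied."""
        out = {}
        for k, w in self.omega_hat.items():
            out[k] = OMEGA_CAP if w >= 0.999 * OMEGA_CAP else w
        return out


@dataclass(frozen=True)
class LRTResult:
    stat: float
    df: int
    p_value: float


def likelihood_ratio_test(
    null: FitResult, alt: FitResult, df: int | None = None, mixture: bool = False
) -> LRTResult:
    """Chi-square likelihood ratio test of a nested model pair.

    ``df`` defaults to the free-parameter difference.  With ``mixture``
    the reference distribution is the 50:50 mix of a point mass at 0 and
    chi-square(1), appropriate for a boundary null such as the
    branch-site test.
    """
    if alt.n_free_params <= null.n_free_params:
        raise NestingError(
            f"alternative must have more free parameters than the null "
            f"({alt.n_free_params} <= {null.n_free_params})"
        )
    stat = 2.0 * (alt.lnL - null.lnL)
    if stat < -1e-4:
        raise NestingError(
            f"alternative lnL {alt.lnL:.6f} below null lnL {null.lnL:.6f}: "
            "models not nested or fit not converged"
        )
    stat = max(stat, 0.0)
    if df is None:
        df = alt.n_free_params - null.n_free_params
    if mixture:
        p = 0.5 * stats.chi2.sf(stat, 1) if stat > 0 else 1.0
    else:
        p = float(stats.chi2.sf(stat, df))
    return LRTResult(stat=stat, df=df, p_value=float(min(max(p, 0.0), 1.0)))


# --------------------------------------------------------------------------
# internal parameter packing
# --------------------------------------------------------------------------


def _log_bounds(lo_hi: tuple[float, float]) -> tuple[float, float]:
    return (math.log(lo_hi[0]), math.log(lo_hi[1]))


class _Objective:
    """Maps an unconstrained-ish parameter vector to -lnL for one family."""

    def __init__(
        self,
        engine: PruningEngine,
        freqs: CodonFrequencies,
        spec: CodonModelSpec,
        fix_omega2: bool = False,
    ) -> None:
        self.engine = engine
        self.freqs = freqs
        self.spec = spec
        self.family = spec.family
        self.branches = engine.branches
        self.fix_omega2 = fix_omega2
        tree = engine.tree
        self.categories = np.array([n.category for n in self.branches])
        self.n_categories = int(self.categories.max()) + 1 if len(self.branches) else 1
        if self.family in (ModelFamily.branch_site_A, ModelFamily.branch_site_A_null):
            fg = sorted(set(self.categories) - {0})
            if len(fg) != 1:
                raise ModelSpecError(
                    "branch-site model requires exactly one foreground category"
                )
        if self.family is ModelFamily.branch:
            present = set(self.categories)
            if present != set(range(self.n_categories)):
                raise ModelSpecError(
                    f"branch categories {sorted(present)} not contiguous: "
                    "some category has no branches"
                )
        # slices of the parameter vector
        self.names: list[str] = ["log_kappa"]
        self.bounds: list[tuple[float, float]] = [_log_bounds(spec.kappa_bounds)]
        wb = _log_bounds(spec.omega_bounds)
        if self.family is ModelFamily.one_ratio:
            self._n_omega = 1
        elif self.family is ModelFamily.branch:
            self._n_omega = self.n_categories
        elif self.family is ModelFamily.free_ratio:
            self._n_omega = len(self.branches)
        else:
            self._n_omega = 0
        for i in range(self._n_omega):
            self.names.append(f"log_omega_{i}")
            self.bounds.append(wb)
        if self.family in (ModelFamily.branch_site_A, ModelFamily.branch_site_A_null):
            # p0, p1 via unconstrained stick weights; omega0 in (0,1]
            self.names += ["alpha_p0", "alpha_p1", "log_omega0"]
            self.bounds += [(-15.0, 15.0), (-15.0, 15.0),
                            (math.log(spec.omega_bounds[0]), 0.0)]
            if self.family is ModelFamily.branch_site_A and not fix_omega2:
                self.names.append("log_omega2")
                self.bounds.append((0.0, math.log(spec.omega_bounds[1])))
        self._bl_offset = len(self.names)
        if spec.estimate_branch_lengths:
            lb = _log_bounds(LENGTH_BOUNDS)
            for i in range(len(self.branches)):
                self.names.append(f"log_t_{i}")
                self.bounds.append(lb)

    # -- vector <-> parameters ------------------------------------------

    def initial(self, rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.empty(len(self.names))
        x[0] = math.log(2.0)
        for i in range(self._n_omega):
            x[1 + i] = math.log(0.4)
        if self.family in (ModelFamily.branch_site_A, ModelFamily.branch_site_A_null):
            j = 1 + self._n_omega
            x[j] = 1.0      # p0 weight
            x[j + 1] = 0.0  # p1 weight
            x[j + 2] = math.log(0.2)
            if self.family is ModelFamily.branch_site_A and not self.fix_omega2:
                x[j + 3] = math.log(1.5)
        if self.spec.estimate_branch_lengths:
            for i, node in enumerate(self.branches):
                t0 = node.length if node.length and node.length > 0 else 0.1
                x[self._bl_offset + i] = math.log(t0)
        if rng is not None:
            x = x + rng.normal(0.0, 0.5, size=x.shape)
            lo = np.array([b[0] for b in self.bounds])
            hi = np.array([b[1] for b in self.bounds])
            x = np.clip(x, lo, hi)
        return x

    def lengths(self, x: np.ndarray) -> dict[int, float] | None:
        if not self.spec.estimate_branch_lengths:
            return None
        return {
            id(node): math.exp(x[self._bl_offset + i])
            for i, node in enumerate(self.branches)
        }

    # -- objective -------------------------------------------------------

    def __call__(self, x: np.ndarray) -> float:
        try:
            return -self._lnL(x)
        except ArithmeticError:
            return 1e12

    def _lnL(self, x: np.ndarray) -> float:
        kappa = math.exp(x[0])
        lengths = self.lengths(x)
        fam = self.family
        if fam in (ModelFamily.one_ratio, ModelFamily.branch, ModelFamily.free_ratio):
            if fam is ModelFamily.one_ratio:
                w = math.exp(x[1])
                omega_fn = lambda node: w
            elif fam is ModelFamily.branch:
                ws = np.exp(x[1 : 1 + self.n_categories])
                omega_fn = lambda node: float(ws[node.category])
            else:
                ws = {id(n): math.exp(x[1 + i]) for i, n in enumerate(self.branches)}
                omega_fn = lambda node: ws[id(node)]
            return self.engine.log_likelihood(self.freqs, kappa, omega_fn, lengths)
        return self._lnL_branch_site(x, kappa, lengths)

    def _branch_site_params(self, x: np.ndarray) -> tuple[float, float, float, float]:
        j = 1 + self._n_omega
        e0, e1 = math.exp(x[j]), math.exp(x[j + 1])
        denom = 1.0 + e0 + e1
        p0, p1 = e0 / denom, e1 / denom
        omega0 = math.exp(x[j + 2])
        if self.family is ModelFamily.branch_site_A and not self.fix_omega2:
            omega2 = math.exp(x[j + 3])
        else:
            omega2 = 1.0
        return p0, p1, omega0, omega2

    def _lnL_branch_site(
        self, x: np.ndarray, kappa: float, lengths: dict | None
    ) -> float:
        p0, p1, omega0, omega2 = self._branch_site_params(x)
        rest = max(1.0 - p0 - p1, 0.0)
        share = p0 + p1
        p2a = rest * (p0 / share) if share > 0 else rest / 2
        p2b = rest * (p1 / share) if share > 0 else rest / 2
        props = np.array([p0, p1, p2a, p2b])
        # (background omega, foreground omega) per site class
        classes = [(omega0, omega0), (1.0, 1.0), (omega0, omega2), (1.0, omega2)]
        site_ll = np.full((4, self.engine.n_patterns), -np.inf)
        for c, (w_bg, w_fg) in enumerate(classes):
            if props[c] <= 0:
                continue
            omega_fn = lambda node: w_fg if node.category > 0 else w_bg
            site_ll[c] = self.engine.site_log_likelihoods(
                self.freqs, kappa, omega_fn, lengths
            )
        with np.errstate(divide="ignore"):
            logp = np.log(props)[:, None]
        mix = logsumexp_rows(logp + site_ll)
        return float(self.engine.weights @ mix)

    # -- bookkeeping -----------------------------------------------------

    def n_free_params(self) -> int:
        n = len(self.names) + self.freqs.n_free_params
        if not self.spec.estimate_branch_lengths:
            return n
        return n  # branch-length coordinates are already in `names`

    def unpack(self, x: np.ndarray, engine: PruningEngine) -> dict:
        kappa = math.exp(x[0])
        fam = self.family
        out: dict = {"kappa": kappa}
        if fam is ModelFamily.one_ratio:
            out["omega"] = {0: math.exp(x[1])}
        elif fam is ModelFamily.branch:
            out["omega"] = {c: math.exp(x[1 + c]) for c in range(self.n_categories)}
        elif fam is ModelFamily.free_ratio:
            out["omega"] = {
                engine.tree.clade_id(n): math.exp(x[1 + i])
                for i, n in enumerate(self.branches)
            }
        else:
            p0, p1, omega0, omega2 = self._branch_site_params(x)
            out["omega"] = {"omega0": omega0, "omega2": omega2}
            out["props"] = (p0, p1)
        if self.spec.estimate_branch_lengths:
            out["lengths"] = {
                engine.tree.clade_id(n): math.exp(x[self._bl_offset + i])
                for i, n in enumerate(self.branches)
            }
        else:
            out["lengths"] = {
                engine.tree.clade_id(n): n.length for n in self.branches
            }
        return out


def logsumexp_rows(a: np.ndarray) -> np.ndarray:
    """logsumexp down axis 0, tolerating -inf rows."""
    m = a.max(axis=0)
    m = np.where(np.isfinite(m), m, 0.0)
    return m + np.log(np.exp(a - m).sum(axis=0))


# --------------------------------------------------------------------------
# public fitting API
# --------------------------------------------------------------------------


def _as_encoded(
    aln: CodonAlignment | np.ndarray, taxa: Sequence[str] | None, code: GeneticCode
) -> tuple[np.ndarray, list[str]]:
    if isinstance(aln, CodonAlignment):
        return encode_codons(aln, code), list(aln.taxa)
    if taxa is None:
        raise ValueError("taxa must accompany a pre-encoded matrix")
    return np.asarray(aln), list(taxa)


def fit_model(
    aln: CodonAlignment | np.ndarray,
    tree: PhyloTree,
    spec: CodonModelSpec,
    seed: int = 0,
    taxa: Sequence[str] | None = None,
    code: GeneticCode = STANDARD_CODE,
    freqs: CodonFrequencies | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one codon model.

    Multi-restart bounded L-BFGS-B on log-transformed parameters; the best
    of ``spec.n_restarts`` jittered starts is returned.  ``freqs`` may be
    supplied to reuse frequencies estimated on a larger data set (the
    scheme must match ``spec.freq_scheme``).
    """
    encoded, taxa_list = _as_encoded(aln, taxa, code)
    if freqs is None:
        freqs = estimate_frequencies(encoded, code, spec.freq_scheme)
    elif freqs.scheme is not spec.freq_scheme:
        raise ModelSpecError("supplied frequencies do not match spec.freq_scheme")
    engine = PruningEngine(encoded, taxa_list, tree, code)
    if spec.family is ModelFamily.free_ratio and len(engine.branches) > 200:
        logger.warning(
            "free-ratio fit over %d branches: expect a long optimization",
            len(engine.branches),
        )
    fix_w2 = spec.family is ModelFamily.branch_site_A_null
    obj = _Objective(engine, freqs, spec, fix_omega2=fix_w2)
    if not spec.estimate_branch_lengths:
        for n in engine.branches:
            if n.length is None:
                raise ModelSpecError(
                    "fixed-branch-length fit requires lengths on every branch"
                )

    rng = np.random.default_rng(seed)
    best = None
    used = 0
    for r in range(max(1, spec.n_restarts)):
        x0 = obj.initial(rng if r > 0 else None)
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B", bounds=obj.bounds,
            options={"maxiter": 1000, "ftol": 1e-10},
        )
        used += 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res

    # categories with (near) zero inferred synonymous change leave the
    # likelihood flat in omega above some point; snap such estimates to the
    # upper bound so they report as the 999 sentinel
    x = best.x.copy()
    f_best = float(best.fun)
    hi = math.log(spec.omega_bounds[1])
    for i, name in enumerate(obj.names):
        if name.startswith("log_omega") and math.log(50.0) < x[i] < hi - 1e-9:
            x_try = x.copy()
            x_try[i] = hi
            f_try = obj(x_try)
            if f_try <= f_best + 1e-3:
                x = x_try
                f_best = min(f_best, f_try)

    params = obj.unpack(x, engine)
    omega = params["omega"]
    return FitResult(
        spec=spec,
        lnL=-f_best,
        kappa_hat=params["kappa"],
        omega_hat=omega,
        branch_lengths_hat=params["lengths"],
        site_class_props=params.get("props"),
        n_free_params=obj.n_free_params(),
        converged=bool(best.success),
        n_restarts_used=used,
    )


def fit_free_ratio(
    aln: CodonAlignment | np.ndarray,
    tree: PhyloTree,
    seed: int = 0,
    taxa: Sequence[str] | None = None,
    code: GeneticCode = STANDARD_CODE,
    freq_scheme: FrequencyScheme = FrequencyScheme.CF0,
    estimate_branch_lengths: bool = True,
    screen_threshold: float = SCREEN_THRESHOLD,
    n_restarts: int = 3,
) -> FitResult:
    """Exploratory free-ratio fit: an independent omega per branch.

    Branches whose capped omega estimate exceeds ``screen_threshold`` are
    listed in ``flagged_branches`` (the elevated-omega screen).
    """
    spec = CodonModelSpec(
        family=ModelFamily.free_ratio,
        freq_scheme=freq_scheme,
        estimate_branch_lengths=estimate_branch_lengths,
        n_restarts=n_restarts,
    )
    fit = fit_model(aln, tree, spec, seed=seed, taxa=taxa, code=code)
    report = fit.omega_report()
    fit.flagged_branches = [k for k, w in report.items() if w > screen_threshold]
    return fit


def fit_branch_site(
    aln: CodonAlignment | np.ndarray,
    tree: PhyloTree,
    alternative: bool,
    seed: int = 0,
    taxa: Sequence[str] | None = None,
    code: GeneticCode = STANDARD_CODE,
    freq_scheme: FrequencyScheme = FrequencyScheme.CF0,
    estimate_branch_lengths: bool = True,
    n_restarts: int = 3,
) -> FitResult:
    """Fit branch-site model A (``alternative=True``) or its omega2=1 null."""
    family = ModelFamily.branch_site_A if alternative else ModelFamily.branch_site_A_null
    spec = CodonModelSpec(
        family=family,
        freq_scheme=freq_scheme,
        estimate_branch_lengths=estimate_branch_lengths,
        n_restarts=n_restarts,
    )
    return fit_model(aln, tree, spec, seed=seed, taxa=taxa, code=code)


def select_frequency_model(
    aln: CodonAlignment | np.ndarray,
    tree: PhyloTree,
    schemes: Sequence[FrequencyScheme | str] = tuple(FrequencyScheme),
    seed: int = 0,
    taxa: Sequence[str] | None = None,
    code: GeneticCode = STANDARD_CODE,
    estimate_branch_lengths: bool = True,
    n_restarts: int = 2,
) -> list[FitResult]:
    """Rank codon-frequency schemes by AIC of a one-ratio fit.

    Ties (within 1e-9) break toward fewer free parameters.  Intended to be
    run on the intact-sequence set, after which the winning scheme is used
    for every per-clade analysis of that gene.
    """
    schemes = [FrequencyScheme(s) for s in schemes]
    if len(schemes) < 2:
        raise ModelSpecError("frequency-model selection needs >= 2 schemes")
    fits = []
    for scheme in schemes:
        spec = CodonModelSpec(
            family=ModelFamily.one_ratio,
            freq_scheme=scheme,
            estimate_branch_lengths=estimate_branch_lengths,
            n_restarts=n_restarts,
        )
        fits.append(fit_model(aln, tree, spec, seed=seed, taxa=taxa, code=code))
    return sorted(fits, key=lambda f: (round(f.aic, 9), f.n_free_params))
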
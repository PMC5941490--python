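"""Codon substitution-model likelihood machinery.

Implements a Goldman–Yang-style codon model over the 61 sense codons:
single-nucleotide changes occur at rate ``pi_j``, multiplied by ``kappa``
for transitions and ``omega`` (dN/dS) for nonsynonymous changes; the
matrix is scaled so one unit of branch length is one expected
substitution per codon at stationarity.  On top of this sit Felsenstein
pruning with site-pattern compression, the F3x4 codon-frequency
estimator, and constrained maximum-likelihood fitting of five standard
hypotheses: one_ratio, two_ratio (foreground branch test), free_ratio,
and the branch-site "model A" null/alternative pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, expm as _scipy_expm
from scipy.optimize import minimize
from scipy.special import expit, logit

from .alignment import CodonAlignment
from .genetics import N_SENSE, codon_change_masks
from .trees import PhyloTree, TreeIndex

__all__ = [
    "CodonModelParams",
    "SiteMixture",
    "ModelFit",
    "build_rate_matrix",
    "transition_matrix",
    "estimate_f3x4",
    "log_likelihood",
    "fit_parameters",
    "branch_ds",
    "substitution_fluxes",
    "HYPOTHESES",
]

HYPOTHESES = ("one_ratio", "two_ratio", "free_ratio", "modelA_null", "modelA_alt")

# optimizer box constraints (log scale for rates/lengths, logit scale for mixtures)
_BOUND_T = (np.log(1e-6), np.log(20.0))
_BOUND_KAPPA = (np.log(0.1), np.log(50.0))
_BOUND_OMEGA = (np.log(1e-4), np.log(50.0))
_BOUND_OMEGA0 = (np.log(1e-4), 0.0)  # purifying class, omega0 <= 1
_BOUND_OMEGA2 = (0.0, np.log(50.0))  # positive-selection class, omega2 >= 1
_BOUND_LOGIT = (-8.0, 8.0)
_PI_FLOOR = 1e-8


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass
class SiteMixture:
    """Branch-site "model A" site-class mixture.

    Four site classes: 0 (omega0 everywhere), 1 (neutral, omega1 = 1
    everywhere), 2a (omega0 on background, omega2 on foreground) and 2b
    (neutral background, omega2 foreground).  ``omega1`` is fixed at 1.
    """

    p0: float
    p1: float
    p2a: float
    p2b: float
    omega0: float
    omega2: float
    omega1: float = 1.0

    def __post_init__(self):
        props = np.array([self.p0, self.p1, self.p2a, self.p2b])
        if np.any(props < -1e-12) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"site-class proportions invalid: {props}")
        if self.omega1 != 1.0:
            raise ValueError("omega1 is fixed at 1 in model A")
        if not (0 <= self.omega0 <= 1.0 + 1e-12):
            raise ValueError("omega0 must lie in [0, 1]")
        if self.omega2 < 1.0 - 1e-12:
            raise ValueError("omega2 must be >= 1")

    @property
    def positive_fraction(self) -> float:
        """Proportion of sites in the foreground positive-selection classes."""
        return self.p2a + self.p2b


@dataclass
class CodonModelParams:
    """Parameters of one codon-model hypothesis.

    ``omega_map`` keys are branch ids or the tokens ``ALL``, ``FOREGROUND``,
    ``BACKGROUND``.  When ``site_mixture`` is present the omegas come from
    the mixture and ``omega_map`` is ignored.
    """

    kappa: float
    omega_map: dict[str, float]
    pi: np.ndarray
    site_mixture: SiteMixture | None = None

    def __post_init__(self):
        if not np.isfinite(self.kappa) or self.kappa <= 0:
            raise ValueError("kappa must be positive and finite")
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (N_SENSE,) or np.any(self.pi < 0):
            raise ValueError("pi must be a non-negative 61-vector")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1 within 1e-9")
        for key, w in self.omega_map.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"omega for {key!r} must be >= 0 and finite")

    def omega_for_branch(self, branch_id: str, is_foreground: bool) -> float:
        if branch_id in self.omega_map:
            return self.omega_map[branch_id]
        token = "FOREGROUND" if is_foreground else "BACKGROUND"
        if token in self.omega_map:
            return self.omega_map[token]
        if "ALL" in self.omega_map:
            return self.omega_map["ALL"]
        raise KeyError(f"no omega for branch {branch_id!r}")


@dataclass
class ModelFit:
    """A maximized codon-model fit."""

    hypothesis: str
    params: CodonModelParams
    branch_lengths: dict[str, float]
    log_likelihood: float
    converged: bool
    n_free_params: int
    foreground: str | None = None
    message: str = ""

    def omega(self, token: str = "ALL") -> float:
        return self.params.omega_map[token]


# --------------------------------------------------------------------------
# rate matrix and transition probabilities
# --------------------------------------------------------------------------


def _validate_pi(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_SENSE,):
        raise ValueError(f"pi must have length {N_SENSE}")
    if not np.all(np.isfinite(pi)) or np.any(pi < 0):
        raise ValueError("pi entries must be finite and non-negative")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError(f"pi must sum to 1 (got {pi.sum():.8f})")
    return pi / pi.sum()


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Instantaneous 61x61 codon rate matrix, scaled to one expected
    substitution per codon at stationarity.

    Off-diagonal rates are zero for multi-nucleotide changes and
    ``pi_j * kappa^[transition] * omega^[nonsynonymous]`` otherwise.
    """
    if not np.isfinite(kappa) or kappa <= 0:
        raise ValueError("kappa must be positive and finite")
    if not np.isfinite(omega) or omega < 0:
        raise ValueError("omega must be non-negative and finite")
    pi = _validate_pi(pi)
    single, transition, synonymous = codon_change_masks()
    rate = np.where(single, pi[np.newaxis, :], 0.0)
    rate = np.where(single & transition, rate * kappa, rate)
    rate = np.where(single & ~synonymous, rate * omega, rate)
    np.fill_diagonal(rate, 0.0)
    np.fill_diagonal(rate, -rate.sum(axis=1))
    scale = -np.dot(pi, np.diag(rate))
    if scale > 0:
        rate /= scale
    return rate


def transition_matrix(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """Transition probability matrix ``expm(Q t)``.

    With ``pi`` supplied the reversible structure is exploited through a
    symmetric eigendecomposition; otherwise a general matrix exponential
    is used.  Rows are clipped/renormalized against roundoff.
    """
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    if pi is not None:
        P = _EigenQ(Q, _validate_pi(pi)).prob(t)
    else:
        P = _scipy_expm(Q * t)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


class _EigenQ:
    """Eigendecomposition of a reversible Q for fast expm at many t."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        piw = np.maximum(pi, _PI_FLOOR)
        sq = np.sqrt(piw)
        B = (sq[:, None] / sq[None, :]) * Q
        B = 0.5 * (B + B.T)  # symmetrize against roundoff
        lam, U = eigh(B)
        self.lam = lam
        self.left = U / sq[:, None]
        self.right = (U * sq[:, None]).T

    def prob(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def unscaled_flux_coeffs(kappa: float, pi: np.ndarray) -> tuple[float, float]:
    """Synonymous and nonsynonymous rate coefficients of the unscaled
    codon matrix, so its total rate at stationarity is ``rs + omega*rn``."""
    single, transition, synonymous = codon_change_masks()
    flux = pi[:, None] * pi[None, :] * np.where(transition, kappa, 1.0)
    rs = float(flux[single & synonymous].sum())
    rn = float(flux[single & ~synonymous].sum())
    return rs, rn


def mixture_effective_lengths(
    kappa: float,
    pi: np.ndarray,
    edge_lengths: np.ndarray,
    classes: list[tuple[float, np.ndarray]],
) -> np.ndarray:
    """Per-class effective branch lengths for a site-class mixture.

    Branch length t is the expected substitutions per codon averaged over
    site classes; a class with omega w then advances by
    ``t * (rs + w*rn) / sum_c p_c (rs + w_c*rn)`` on that branch.  With a
    single class this reduces to t itself.
    """
    rs, rn = unscaled_flux_coeffs(kappa, pi)
    probs = np.array([max(p, 0.0) for p, _ in classes])
    W = np.stack([omegas for _, omegas in classes])
    if rs + rn <= 0.0:  # degenerate frequencies: no substitution is possible
        return np.tile(edge_lengths, (len(classes), 1))
    rates = rs + W * rn
    total = probs.sum()
    rho = (probs[:, None] * rates).sum(axis=0) / (total if total > 0 else 1.0)
    return edge_lengths[None, :] * rates / np.maximum(rho[None, :], 1e-300)


# --------------------------------------------------------------------------
# codon frequencies
# --------------------------------------------------------------------------


def estimate_f3x4(alignment: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies: position-specific nucleotide frequencies
    multiplied across the three codon positions, stop codons zeroed,
    renormalized over the 61 sense codons."""
    from .genetics import NUCLEOTIDES, STANDARD_CODE

    counts = np.zeros((3, 4))
    nt_index = {n: k for k, n in enumerate(NUCLEOTIDES)}
    for row in alignment.rows:
        for s in range(len(row) // 3):
            codon = row[3 * s : 3 * s + 3]
            if all(ch in nt_index for ch in codon):
                for p, ch in enumerate(codon):
                    counts[p, nt_index[ch]] += 1
    if counts.sum() == 0:
        raise ValueError("alignment has no unambiguous, non-gap codons")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]] * freqs[2, nt_index[c[2]]]
            for c in STANDARD_CODE.sense_codons
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate composition: all sense-codon frequencies zero")
    return pi / total


# --------------------------------------------------------------------------
# pruning likelihood
# --------------------------------------------------------------------------


class LikelihoodEngine:
    """Pruning likelihood for one (alignment, tree) pair.

    Compresses alignment columns to unique site patterns once, then
    evaluates mixture log-likelihoods for arbitrary (kappa, branch
    lengths, per-class branch omega assignment) combinations.  Rooted
    binary input trees are derooted first, since under a reversible model
    the two root-adjacent branch lengths are only jointly identifiable.
    """

    def __init__(self, alignment: CodonAlignment, tree: PhyloTree):
        work = tree.copy()
        root = work.tree.seed_node
        if len(root.child_nodes()) == 2 and len(work.leaf_names) > 2:
            work.tree.deroot()
        self.tree = work
        missing = set(alignment.taxa) - set(work.leaf_names)
        if missing:
            raise ValueError(f"alignment taxa absent from tree: {sorted(missing)}")
        extra = set(work.leaf_names) - set(alignment.taxa)
        if extra:
            raise ValueError(f"tree leaves absent from alignment: {sorted(extra)}")

        self.index: TreeIndex = work.postorder_index()
        self.children = self.index.children()
        self.edge_nodes = self.index.edge_nodes
        self.edge_branch_ids = [self.index.branch_ids[k] for k in self.edge_nodes]
        self.n_edges = len(self.edge_nodes)

        codes = alignment.codes()
        row_of = {t: i for i, t in enumerate(alignment.taxa)}
        leaf_nodes = sorted(self.index.leaf_index.values())
        leaf_codes = np.stack(
            [
                codes[row_of[name]]
                for name, k in sorted(self.index.leaf_index.items(), key=lambda kv: kv[1])
            ]
        )
        patterns, self.weights = np.unique(leaf_codes, axis=1, return_counts=True)
        self.n_patterns = patterns.shape[1]
        # per-leaf conditional likelihoods (61, n_patterns); missing -> all ones
        self.leaf_partials: dict[int, np.ndarray] = {}
        for r, k in enumerate(leaf_nodes):
            part = np.zeros((N_SENSE, self.n_patterns))
            obs = patterns[r]
            miss = obs < 0
            part[:, miss] = 1.0
            cols = np.nonzero(~miss)[0]
            part[obs[cols], cols] = 1.0
            self.leaf_partials[k] = part
        self._eig_cache: dict[tuple[float, float], _EigenQ] = {}
        self._pi: np.ndarray | None = None

    def set_pi(self, pi: np.ndarray) -> None:
        pi = _validate_pi(pi)
        if self._pi is None or not np.array_equal(pi, self._pi):
            self._pi = pi
            self._eig_cache.clear()

    def _eig(self, kappa: float, omega: float) -> _EigenQ:
        key = (round(float(kappa), 12), round(float(omega), 12))
        eig = self._eig_cache.get(key)
        if eig is None:
            eig = _EigenQ(build_rate_matrix(kappa, omega, self._pi), self._pi)
            if len(self._eig_cache) > 512:
                self._eig_cache.clear()
            self._eig_cache[key] = eig
        return eig

    def loglike(
        self,
        kappa: float,
        edge_lengths: np.ndarray,
        classes: list[tuple[float, np.ndarray]],
    ) -> float:
        """Mixture log-likelihood.

        ``classes`` is a list of ``(probability, omega_per_edge)`` pairs;
        ``omega_per_edge`` aligns with ``edge_branch_ids``.  Branch
        lengths are expected substitutions per codon averaged over site
        classes, so relative rates between classes are preserved (a
        positive-selection class evolves faster than average): each
        class's transition matrix uses the effective length
        ``t * r(omega_class) / mean_class_rate`` on that branch.
        """
        pi = self._pi
        edge_pos = {k: e for e, k in enumerate(self.edge_nodes)}
        eff_lengths = mixture_effective_lengths(kappa, pi, edge_lengths, classes)
        site_ll = np.full((len(classes), self.n_patterns), -np.inf)
        for ci, (prob, omegas) in enumerate(classes):
            if prob <= 0:
                continue
            probs_mats = {}
            for e in range(self.n_edges):
                key = (omegas[e], eff_lengths[ci, e])
                if key not in probs_mats:
                    probs_mats[key] = self._eig(kappa, omegas[e]).prob(eff_lengths[ci, e])
            logscale = np.zeros(self.n_patterns)
            partials: dict[int, np.ndarray] = {}
            for k in range(self.index.n_nodes):
                kids = self.children[k]
                if not kids:
                    partials[k] = self.leaf_partials[k]
                    continue
                part = np.ones((N_SENSE, self.n_patterns))
                for c in kids:
                    e = edge_pos[c]
                    key = (omegas[e], eff_lengths[ci, e])
                    part *= probs_mats[key] @ partials.pop(c)
                m = part.max(axis=0)
                bad = m <= 0
                if np.any(bad):
                    m = np.where(bad, 1.0, m)
                part /= m
                with np.errstate(divide="ignore"):
                    logscale += np.where(bad, -np.inf, np.log(m))
                partials[k] = part
            root_part = partials[self.index.root]
            lik = pi @ root_part
            with np.errstate(divide="ignore"):
                site_ll[ci] = np.log(lik) + logscale
        probs = np.array([p for p, _ in classes])
        m = site_ll.max(axis=0)
        m = np.where(np.isfinite(m), m, 0.0)
        with np.errstate(invalid="ignore"):
            mix = m + np.log((np.exp(site_ll - m) * probs[:, None]).sum(axis=0))
        return float(self.weights @ mix)

    # --------------------------------------------------- class assembly

    def classes_for(
        self, params: CodonModelParams, foreground: str | None
    ) -> list[tuple[float, np.ndarray]]:
        fg_flags = np.array([bid == foreground for bid in self.edge_branch_ids])
        if foreground is not None and not fg_flags.any():
            raise KeyError(f"foreground branch {foreground!r} not on (derooted) tree")
        mix = params.site_mixture
        if mix is None:
            omegas = np.array(
                [
                    params.omega_for_branch(bid, bool(fg))
                    for bid, fg in zip(self.edge_branch_ids, fg_flags)
                ]
            )
            return [(1.0, omegas)]
        w0, w2 = mix.omega0, mix.omega2
        bg = ~fg_flags
        def assign(bg_w, fg_w):
            return np.where(bg, bg_w, fg_w)
        return [
            (mix.p0, assign(w0, w0)),
            (mix.p1, assign(1.0, 1.0)),
            (mix.p2a, assign(w0, w2)),
            (mix.p2b, assign(1.0, w2)),
        ]


def log_likelihood(
    alignment: CodonAlignment,
    tree: PhyloTree,
    params: CodonModelParams,
    foreground: str | None = None,
) -> float:
    """Felsenstein-pruning log-likelihood of an alignment on a tree."""
    engine = LikelihoodEngine(alignment, tree)
    engine.set_pi(params.pi)
    lengths = engine.tree.branch_lengths
    t = np.array([lengths[bid] for bid in engine.edge_branch_ids])
    return engine.loglike(params.kappa, t, engine.classes_for(params, foreground))


# --------------------------------------------------------------------------
# maximum-likelihood fitting
# --------------------------------------------------------------------------


def _mixture_from_logits(a: float, b: float) -> tuple[float, float, float, float]:
    """Map two unconstrained logits to the model-A simplex (p0, p1, p2a, p2b).

    ``a`` controls the total mass of classes 0+1; ``b`` the 0-vs-1 split,
    which also divides the foreground class 2 into 2a/2b (PAML's
    convention: p2a : p2b = p0 : p1).
    """
    p01 = expit(a)
    r = expit(b)
    p2 = 1.0 - p01
    return p01 * r, p01 * (1.0 - r), p2 * r, p2 * (1.0 - r)


def _pack_spec(hypothesis: str, n_edges: int):
    """Bounds and extra-parameter layout for each hypothesis."""
    bounds = [_BOUND_T] * n_edges + [_BOUND_KAPPA]
    if hypothesis == "one_ratio":
        bounds += [_BOUND_OMEGA]
    elif hypothesis == "two_ratio":
        bounds += [_BOUND_OMEGA, _BOUND_OMEGA]
    elif hypothesis == "free_ratio":
        bounds += [_BOUND_OMEGA] * n_edges
    elif hypothesis == "modelA_null":
        bounds += [_BOUND_OMEGA0, _BOUND_LOGIT, _BOUND_LOGIT]
    elif hypothesis == "modelA_alt":
        bounds += [_BOUND_OMEGA0, _BOUND_LOGIT, _BOUND_LOGIT, _BOUND_OMEGA2]
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}; choose from {HYPOTHESES}")
    return bounds


def _unpack(hypothesis, x, engine, fg_mask):
    n_edges = engine.n_edges
    t = np.exp(x[:n_edges])
    kappa = float(np.exp(x[n_edges]))
    extra = x[n_edges + 1 :]
    if hypothesis == "one_ratio":
        classes = [(1.0, np.full(n_edges, np.exp(extra[0])))]
        mixture = None
        omega_map = {"ALL": float(np.exp(extra[0]))}
    elif hypothesis == "two_ratio":
        w_bg, w_fg = np.exp(extra[0]), np.exp(extra[1])
        classes = [(1.0, np.where(fg_mask, w_fg, w_bg))]
        mixture = None
        omega_map = {"BACKGROUND": float(w_bg), "FOREGROUND": float(w_fg)}
    elif hypothesis == "free_ratio":
        ws = np.exp(extra)
        classes = [(1.0, ws)]
        mixture = None
        omega_map = {bid: float(w) for bid, w in zip(engine.edge_branch_ids, ws)}
    else:
        w0 = float(np.exp(extra[0]))
        p0, p1, p2a, p2b = _mixture_from_logits(extra[1], extra[2])
        w2 = float(np.exp(extra[3])) if hypothesis == "modelA_alt" else 1.0
        mixture = SiteMixture(p0=p0, p1=p1, p2a=p2a, p2b=p2b, omega0=w0, omega2=max(w2, 1.0))
        classes = [
            (p0, np.full(n_edges, w0)),
            (p1, np.full(n_edges, 1.0)),
            (p2a, np.where(fg_mask, w2, w0)),
            (p2b, np.where(fg_mask, w2, 1.0)),
        ]
        omega_map = {}
    return t, kappa, classes, omega_map, mixture


def _initial_vector(hypothesis, engine, init, rng, jitter, variant=0):
    n_edges = engine.n_edges
    lengths = engine.tree.branch_lengths
    t0 = np.array([max(lengths.get(bid, 0.0), 0.0) or 0.1 for bid in engine.edge_branch_ids])
    kappa0, omega0 = 2.0, 0.4
    mix0 = (0.0, 1.0)  # logits: p01 = .5 split evenly... overridden below
    if init is not None:
        t0 = np.array([init.branch_lengths.get(bid, t) for bid, t in zip(engine.edge_branch_ids, t0)])
        kappa0 = init.params.kappa
        if init.params.omega_map:
            omega0 = float(np.median(list(init.params.omega_map.values())))
    x = list(np.log(np.clip(t0, 1.1e-6, 19.9)))
    x.append(np.log(np.clip(kappa0, 0.11, 49.0)))
    w = np.clip(omega0, 1.1e-4, 49.0)
    if hypothesis == "one_ratio":
        x += [np.log(w)]
    elif hypothesis == "two_ratio":
        x += [np.log(w), np.log(w)]
    elif hypothesis == "free_ratio":
        x += [np.log(w)] * n_edges
    else:
        w0 = np.clip(min(w, 0.5), 1.1e-4, 0.999)
        p0, p1 = 0.65, 0.25
        if init is not None and init.params.site_mixture is not None:
            m = init.params.site_mixture
            w0 = np.clip(m.omega0, 1.1e-4, 0.999)
            tot = max(m.p0 + m.p1, 1e-6)
            p0, p1 = max(m.p0, 1e-4), max(m.p1, 1e-4)
            p0, p1 = tot * p0 / (p0 + p1), tot * p1 / (p0 + p1)
        p01 = p0 + p1
        w2 = 2.5
        if hypothesis == "modelA_alt":
            # starting at (p2 ~ 0, omega2 ~ 1) is a saddle of the alternative;
            # keep some mass in the foreground class and omega2 off the boundary.
            # The alternative surface is multimodal, so structured start
            # variants probe a strong-selection mode as well.
            p01 = min(p01, 0.9)
            if variant == 1:
                p01, w2 = 0.7, 8.0
        a = logit(np.clip(p01, 1e-3, 1 - 1e-3))
        b = logit(np.clip(p0 / (p0 + p1), 1e-3, 1 - 1e-3))
        x += [np.log(w0), a, b]
        if hypothesis == "modelA_alt":
            if init is not None and init.params.site_mixture is not None and variant != 1:
                w2 = max(init.params.site_mixture.omega2, 2.5)
            x += [np.log(np.clip(w2, 1.0 + 1e-6, 49.0))]
    x = np.array(x)
    if jitter > 0:
        x = x + rng.normal(0.0, jitter, size=x.size)
    return x


def fit_parameters(
    alignment: CodonAlignment,
    tree: PhyloTree,
    hypothesis: str,
    foreground: str | None = None,
    *,
    pi: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 0,
    init: ModelFit | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> ModelFit:
    """Maximize the codon-model likelihood under one hypothesis.

    Branch lengths are re-estimated under every hypothesis; codon
    frequencies are fixed at their F3x4 estimates.  Optimization is
    bounded L-BFGS-B on log/logit-transformed parameters with
    ``n_starts`` seeded starts (the first from ``init`` or heuristics,
    the rest jittered).  Non-convergence is reported on the returned fit,
    never silently ignored.
    """
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if hypothesis in ("two_ratio", "modelA_null", "modelA_alt") and foreground is None:
        raise ValueError(f"{hypothesis} requires a foreground branch")
    if alignment.n_taxa < 2:
        raise ValueError("alignment must contain at least 2 taxa")

    engine = LikelihoodEngine(alignment, tree)
    if foreground is not None:
        foreground = tree.resolve_branch(foreground)
    fg_mask = np.array([bid == foreground for bid in engine.edge_branch_ids])
    if foreground is not None and not fg_mask.any():
        raise KeyError(f"foreground branch {foreground!r} not found on the tree")

    pi = estimate_f3x4(alignment) if pi is None else _validate_pi(pi)
    engine.set_pi(pi)
    bounds = _pack_spec(hypothesis, engine.n_edges)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(x):
        t, kappa, classes, _, _ = _unpack(hypothesis, x, engine, fg_mask)
        ll = engine.loglike(kappa, t, classes)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    messages = []
    degenerate = engine.n_patterns == 1
    for s in range(max(1, n_starts)):
        x0 = np.clip(
            _initial_vector(
                hypothesis, engine, init, rng,
                jitter=0.0 if s <= 1 else 0.5, variant=s,
            ),
            lo, hi,
        )
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
        )
        messages.append(str(res.message))
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    t, kappa, _, omega_map, mixture = _unpack(hypothesis, best.x, engine, fg_mask)
    branch_lengths = dict(zip(engine.edge_branch_ids, map(float, t)))
    n_free = engine.n_edges + 1 + {
        "one_ratio": 1,
        "two_ratio": 2,
        "free_ratio": engine.n_edges,
        "modelA_null": 3,
        "modelA_alt": 4,
    }[hypothesis]
    converged = bool(best.success) and not degenerate
    msg = "; ".join(dict.fromkeys(messages))
    if degenerate:
        msg = "degenerate alignment (single site pattern); " + msg
        warnings.warn("degenerate alignment: all codon columns identical", stacklevel=2)
    params = CodonModelParams(kappa=kappa, omega_map=omega_map, pi=pi, site_mixture=mixture)
    return ModelFit(
        hypothesis=hypothesis,
        params=params,
        branch_lengths=branch_lengths,
        log_likelihood=float(-best.fun),
        converged=converged,
        n_free_params=n_free,
        foreground=foreground,
        message=msg,
    )


def fits_to_frame(fits: list[ModelFit]) -> "pd.DataFrame":
    """Tabulate fits (gene rows are supplied via ``ModelFit.foreground``/caller)."""
    import pandas as pd

    rows = []
    for fit in fits:
        row = {
            "hypothesis": fit.hypothesis,
            "lnL": fit.log_likelihood,
            "kappa": fit.params.kappa,
            "converged": fit.converged,
            "n_free_params": fit.n_free_params,
            "foreground": fit.foreground,
        }
        for key, val in fit.params.omega_map.items():
            row[f"omega[{key}]"] = val
        mix = fit.params.site_mixture
        if mix is not None:
            row.update(
                p0=mix.p0, p1=mix.p1, p2a=mix.p2a, p2b=mix.p2b,
                omega0=mix.omega0, omega2=mix.omega2,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# synonymous/nonsynonymous flux and per-branch dS
# --------------------------------------------------------------------------


def substitution_fluxes(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """Expected synonymous and nonsynonymous substitution rates per codon
    (per unit branch length) under the scaled rate matrix."""
    Q = build_rate_matrix(kappa, omega, pi)
    _, _, synonymous = codon_change_masks()
    flux = pi[:, None] * Q
    rho_s = float(flux[synonymous].sum())
    single, _, _ = codon_change_masks()
    rho_n = float(flux[single & ~synonymous].sum())
    return rho_s, rho_n


def branch_ds(fit: ModelFit) -> dict[str, float]:
    """Per-branch dS (synonymous substitutions per synonymous site) from a
    free-ratio (or any per-branch) fit.

    Synonymous site content is measured at omega = 1 with the fitted kappa
    and frequencies, the usual ML-codon-model convention.
    """
    pi = fit.params.pi
    kappa = fit.params.kappa
    rho_s1, rho_n1 = substitution_fluxes(kappa, 1.0, pi)
    f_s = rho_s1 / (rho_s1 + rho_n1)  # fraction of "sites" that are synonymous
    out = {}
    for bid, t in fit.branch_lengths.items():
        omega = fit.params.omega_map.get(bid, fit.params.omega_map.get("ALL"))
        if omega is None:
            raise KeyError(f"fit has no omega for branch {bid!r}")
        rho_s, _ = substitution_fluxes(kappa, omega, pi)
        out[bid] = t * rho_s / (3.0 * f_s)
    return out
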
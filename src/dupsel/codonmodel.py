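"""GY94-style codon substitution models, tree likelihoods and branch-site tests.

The model family covers M0 (a single dN/dS ratio omega for all sites and
branches) and the branch-site "Model A" pair used to test for episodic
positive selection: four site classes {0, 1, 2a, 2b} with

    class 0 : omega0 (< 1)  on background and foreground branches
    class 1 : 1             on background and foreground branches
    class 2a: omega0 background, omega2 foreground
    class 2b: 1     background, omega2 foreground

with proportions (p0, p1, p2a, p2b) where the class-2 mass 1 - p0 - p1 is
split proportionally to p0:p1.  The alternative model estimates omega2 >= 1;
the null fixes omega2 = 1, giving a one-degree-of-freedom likelihood-ratio
test evaluated against chi-square(1) (a deliberately conservative convention;
the 50:50 boundary mixture is available via ``null_distribution``).

Likelihoods use Felsenstein pruning over the 61 sense-codon states with
site-pattern compression and per-node rescaling.  Rate matrices are
diagonalized in the pi-symmetrized basis, so transition matrices for all
branch lengths come from one eigendecomposition per distinct omega.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize
from scipy.special import logsumexp
from scipy.stats import chi2 as chi2_dist

from dupsel.codon import (CodonAlignment, GeneticCode, is_unambiguous_codon,
                          iter_codons, standard_code)
from dupsel.trees import Node, PhyloTree

CLASS_NAMES = ("0", "1", "2a", "2b")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_MIN_T = 1e-8


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class CodonModelSpec:
    """Which model family to fit and which codon-frequency mode to use."""

    model_family: str = "M0"  # M0 | branch_site_alt | branch_site_null
    frequency_mode: str = "F3x4"  # equal | F3x4 | F61

    def __post_init__(self) -> None:
        if self.model_family not in ("M0", "branch_site_alt", "branch_site_null"):
            raise ValueError(f"unknown model family {self.model_family!r}")
        if self.frequency_mode not in ("equal", "F3x4", "F61"):
            raise ValueError(f"unknown frequency mode {self.frequency_mode!r}")

    @property
    def is_branch_site(self) -> bool:
        return self.model_family.startswith("branch_site")

    def label(self) -> str:
        if self.model_family == "M0":
            return "M0"
        return "BS w2>1" if self.model_family == "branch_site_alt" else "BS w2=1"


@dataclass
class CodonModelParams:
    """Codon-model parameter values.

    ``omega0`` doubles as M0's single omega.  ``pi`` holds the 61
    sense-codon stationary frequencies in the lexicographic codon order of
    :meth:`dupsel.codon.GeneticCode.sense_codons`.
    """

    kappa: float
    pi: np.ndarray
    omega0: float
    omega2: Optional[float] = None
    p0: Optional[float] = None
    p1: Optional[float] = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.pi.shape != (61,) or abs(self.pi.sum() - 1.0) > 1e-6 or (self.pi < 0).any():
            raise ValueError("pi must be 61 nonnegative frequencies summing to 1")
        if self.omega0 < 0:
            raise ValueError("omega must be nonnegative")
        if self.omega2 is not None and self.omega2 < 1.0 - 1e-9:
            raise ValueError("omega2 must be >= 1")
        if self.p0 is not None:
            if self.p1 is None:
                raise ValueError("p0 and p1 must be given together")
            if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1 and self.p0 + self.p1 <= 1 + 1e-9):
                raise ValueError("p0, p1 must lie in the simplex")

    @property
    def omega(self) -> float:
        """M0 alias for the single dN/dS ratio."""
        return self.omega0

    def class_proportions(self) -> np.ndarray:
        """Proportions of site classes (0, 1, 2a, 2b)."""
        if self.p0 is None:
            raise ValueError("class proportions require branch-site parameters")
        p2 = max(0.0, 1.0 - self.p0 - self.p1)
        denom = self.p0 + self.p1
        if denom <= 0:
            return np.array([0.0, 0.0, 0.5 * p2, 0.5 * p2])
        return np.array([self.p0, self.p1,
                         p2 * self.p0 / denom, p2 * self.p1 / denom])


@dataclass
class ModelFit:
    """A fitted codon model: parameters, branch lengths and log-likelihood."""

    spec: CodonModelSpec
    params: CodonModelParams
    branch_lengths: dict[str, float]
    lnL: float
    converged: bool
    n_restarts_used: int = 0
    aln: Optional[CodonAlignment] = field(default=None, repr=False)
    tree: Optional[PhyloTree] = field(default=None, repr=False)


@dataclass
class LRTResult:
    """Branch-site likelihood-ratio test result for one foreground branch."""

    foreground_branch: str
    stat: float
    df: int
    p_raw: float
    p_adjusted: Optional[float] = None
    lnL_alt: float = math.nan
    lnL_null: float = math.nan
    converged: bool = True
    fit_alt: Optional[ModelFit] = field(default=None, repr=False)
    fit_null: Optional[ModelFit] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# rate-matrix structure

_STRUCT_CACHE: dict = {}


def _structure(code: GeneticCode):
    """Index arrays of single-base changes among the sense codons."""
    key = (frozenset(code.table.items()), code.stop_codons)
    cached = _STRUCT_CACHE.get(key)
    if cached is not None:
        return cached
    codons = code.sense_codons
    index = {c: i for i, c in enumerate(codons)}
    rows, cols, ts, syn = [], [], [], []
    for i, c1 in enumerate(codons):
        for pos in range(3):
            for base in "ACGT":
                if base == c1[pos]:
                    continue
                c2 = c1[:pos] + base + c1[pos + 1:]
                j = index.get(c2)
                if j is None:  # stop codon target: rate 0
                    continue
                rows.append(i)
                cols.append(j)
                ts.append((c1[pos], base) in _TRANSITIONS)
                syn.append(code.translate(c1) == code.translate(c2))
    out = (np.array(rows), np.array(cols),
           np.array(ts, dtype=bool), np.array(syn, dtype=bool))
    _STRUCT_CACHE[key] = out
    return out


def _raw_rate_matrix(kappa: float, pi: np.ndarray, omega: float,
                     code: GeneticCode) -> np.ndarray:
    rows, cols, ts, syn = _structure(code)
    rates = pi[cols].astype(float).copy()
    rates[ts] *= kappa
    rates[~syn] *= omega
    Q = np.zeros((61, 61))
    Q[rows, cols] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def mean_rate(kappa: float, pi: np.ndarray, omega: float,
              code: GeneticCode | None = None) -> float:
    """Expected substitutions per codon per unit time at stationarity."""
    code = code or standard_code()
    Q = _raw_rate_matrix(kappa, pi, omega, code)
    return float(-(pi * np.diag(Q)).sum())


def build_rate_matrix(params: CodonModelParams, omega: float,
                      code: GeneticCode | None = None,
                      scale: bool | float = True) -> np.ndarray:
    """61x61 GY94 generator: pi_j (kappa for transitions, omega for nonsyn).

    With ``scale=True`` the matrix is normalized so the mean substitution
    rate at stationarity is 1 (branch lengths in expected substitutions per
    codon); a float rescales by that factor instead (used for joint scaling
    of mixture-model class matrices).
    """
    code = code or standard_code()
    pi = np.asarray(params.pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError("codon frequencies must sum to 1")
    Q = _raw_rate_matrix(params.kappa, pi, omega, code)
    if scale is True:
        mu = -(pi * np.diag(Q)).sum()
        if mu > 0:
            Q = Q / mu
    elif scale is not False:
        Q = Q / float(scale)
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Qt); rows sum to 1, entries clipped at 0."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    P = linalg.expm(Q * t)
    P = np.maximum(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# stationary frequencies

def stationary_frequencies(aln: CodonAlignment, mode: str,
                           code: GeneticCode | None = None,
                           ids: Optional[Sequence[str]] = None) -> np.ndarray:
    """Sense-codon frequencies: equal, F3x4 or F61, with small pseudocounts."""
    code = code or standard_code()
    codons = code.sense_codons
    if mode == "equal":
        return np.full(61, 1.0 / 61)
    seqs = [aln.sequence(i) for i in ids] if ids else aln.seqs
    if mode == "F3x4":
        counts = {pos: {b: 0.5 for b in "ACGT"} for pos in range(3)}
        for seq in seqs:
            for codon in iter_codons(seq):
                if is_unambiguous_codon(codon):
                    for pos in range(3):
                        counts[pos][codon[pos]] += 1.0
        freqs = {pos: {b: v / sum(counts[pos].values()) for b, v in counts[pos].items()}
                 for pos in range(3)}
        pi = np.array([freqs[0][c[0]] * freqs[1][c[1]] * freqs[2][c[2]] for c in codons])
    elif mode == "F61":
        tally = {c: 0.1 for c in codons}
        for seq in seqs:
            for codon in iter_codons(seq):
                if codon in tally:
                    tally[codon] += 1.0
        pi = np.array([tally[c] for c in codons])
    else:
        raise ValueError(f"unknown frequency mode {mode!r}")
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# likelihood engine

class _EigenQ:
    """Eigendecomposition of a reversible generator in the pi-symmetric basis.

    Stores the unscaled generator's spectrum; a joint rate-scaling factor
    only rescales the eigenvalues, so the same decomposition serves every
    scaling (and every branch length) without refactorization.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        lam, U = np.linalg.eigh(0.5 * (S + S.T))
        self.lam = lam
        self.A = U / sqrt_pi[:, None]
        self.B = U.T * sqrt_pi[None, :]
        self.mu = float(-(pi * np.diag(Q)).sum())  # mean rate at stationarity

    def transition_matrices(self, ts: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """Stack of P(t/scale) for each branch length; shape (n, 61, 61)."""
        E = np.exp(np.outer(np.asarray(ts, dtype=float) / scale, self.lam))
        P = (self.A[None, :, :] * E[:, None, :]) @ self.B
        return np.maximum(P, 0.0)


class LikelihoodEngine:
    """Pruning likelihood for one (alignment, tree, model-spec) triple.

    Site patterns are compressed; columns containing gaps or ambiguity
    codes in any tree tip are dropped from the likelihood (and recorded in
    ``dropped_columns``).  For branch-site models with a single foreground
    branch the tree is rerooted at the foreground branch's parent so the
    four site classes share the two background prunings.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree, spec: CodonModelSpec,
                 code: GeneticCode | None = None,
                 pi: Optional[np.ndarray] = None,
                 canonicalize: bool = True):
        self.code = code or standard_code()
        self.spec = spec
        tips = tree.tip_names()
        missing = [t for t in tips if t not in aln.ids]
        if missing:
            raise ValueError(f"tree tips missing from alignment: {missing}")
        if spec.is_branch_site and not tree.foreground:
            raise ValueError("branch-site model requires a marked foreground branch")

        named = tree.unrooted_canonical() if canonicalize else tree.copy()
        if not canonicalize:
            for node in named.preorder():
                if node.name is None:
                    node.name = f"node{node.id}"
        fg = named.foreground
        self._single_fg = canonicalize and len(fg) == 1
        if self._single_fg and fg[0].parent is not None and fg[0].parent.parent is not None:
            self.tree = named.rerooted_at(fg[0].parent.label)
        else:
            self.tree = named

        codon_index = {c: i for i, c in enumerate(self.code.sense_codons)}
        cols = []
        self.kept_columns: list[int] = []
        self.dropped_columns: list[int] = []
        seqs = {t: aln.sequence(t) for t in tips}
        for j in range(aln.n_codons):
            column = [seqs[t][3 * j:3 * j + 3] for t in tips]
            if all(c in codon_index for c in column):
                cols.append([codon_index[c] for c in column])
                self.kept_columns.append(j)
            else:
                self.dropped_columns.append(j)
        if not cols:
            raise ValueError("no usable (gap-free) codon columns")
        data = np.array(cols).T  # (ntips, ncols)
        patterns, inverse, counts = np.unique(data, axis=1,
                                              return_inverse=True, return_counts=True)
        self.patterns = patterns
        self.pattern_of_column = inverse
        self.counts = counts.astype(float)
        self.n_sites = data.shape[1]
        self.tip_order = tips
        self.pi = (np.asarray(pi, dtype=float) if pi is not None
                   else stationary_frequencies(aln, spec.frequency_mode, self.code, ids=tips))

        # postorder node bookkeeping on the (possibly rerooted) working tree;
        # branches are keyed by the tip-set split they induce, which is
        # invariant to root placement, so fitted branch lengths transfer
        # between engines built on rerooted copies of the same topology
        self.postorder_nodes = [n for n in self.tree.postorder()]
        self.branch_nodes = [n for n in self.postorder_nodes if n.parent is not None]
        keys = edge_split_keys(self.tree)
        self.branch_labels = [keys[n.id] for n in self.branch_nodes]
        self._tip_codes = {n.label: self.patterns[tips.index(n.label)]
                           for n in self.tree.tips()}
        self._eig_cache: dict[tuple[float, float], _EigenQ] = {}

    def _eig(self, kappa: float, omega: float) -> _EigenQ:
        key = (float(kappa), float(omega))
        eig = self._eig_cache.get(key)
        if eig is None:
            eig = _EigenQ(_raw_rate_matrix(kappa, self.pi, float(omega), self.code),
                          self.pi)
            if len(self._eig_cache) > 64:
                self._eig_cache.clear()
            self._eig_cache[key] = eig
        return eig

    # -- matrices ----------------------------------------------------------
    def _branch_lengths_vector(self, branch_lengths: Optional[dict[str, float]]) -> np.ndarray:
        if branch_lengths is None:
            ts = np.array([n.length for n in self.branch_nodes])
        else:
            ts = np.array([branch_lengths[lbl] for lbl in self.branch_labels])
        return np.maximum(ts, 0.0)

    def _propagate(self, node: Node, P_for: dict[int, np.ndarray]):
        """Partial likelihood contribution of ``node`` to its parent."""
        P = P_for[node.id]
        if node.is_tip:
            return P[:, self._tip_codes[node.label]], 0.0
        part, scale = self._partial(node, P_for)
        return P @ part, scale

    def _partial(self, node: Node, P_for: dict[int, np.ndarray]):
        part = np.ones((61, self.patterns.shape[1]))
        scale = np.zeros(self.patterns.shape[1])
        for child in node.children:
            contrib, s = self._propagate(child, P_for)
            part = part * contrib
            scale = scale + s
        m = part.max(axis=0)
        m = np.where(m > 0, m, 1.0)
        part = part / m
        scale = scale + np.log(m)
        return part, scale

    def _root_partial_single(self, kappa: float, omega_per_branch: np.ndarray,
                             ts: np.ndarray, scale_factor: float):
        """Root partial likelihoods for one deterministic omega assignment."""
        P_for: dict[int, np.ndarray] = {}
        for w in np.unique(omega_per_branch):
            sel = omega_per_branch == w
            Ps = self._eig(kappa, float(w)).transition_matrices(ts[sel], scale_factor)
            for node, P in zip([n for n, m in zip(self.branch_nodes, sel) if m], Ps):
                P_for[node.id] = P
        return self._partial(self.tree.root, P_for)

    def _pattern_loglikes_single(self, kappa: float, omega_per_branch: np.ndarray,
                                 ts: np.ndarray, scale_factor: float) -> np.ndarray:
        """log P(pattern) for one deterministic omega assignment per branch."""
        part, scale = self._root_partial_single(kappa, omega_per_branch, ts, scale_factor)
        site = self.pi @ part
        return np.log(np.maximum(site, 1e-300)) + scale

    def _class_assignments_and_weights(self, params: CodonModelParams):
        if self.spec.model_family == "M0":
            scale = self._eig(params.kappa, params.omega0).mu
            return [(params.omega0, params.omega0)], np.array([1.0]), max(scale, 1e-12)
        w0 = params.omega0
        w2 = params.omega2 if params.omega2 is not None else 1.0
        weights = params.class_proportions()
        mus = {w: self._eig(params.kappa, w).mu for w in {w0, 1.0}}
        scale = ((weights[0] + weights[2]) * mus[w0]
                 + (weights[1] + weights[3]) * mus[1.0])
        return [(w0, w0), (1.0, 1.0), (w0, w2), (1.0, w2)], weights, max(scale, 1e-12)

    def class_root_log_partials(self, params: CodonModelParams,
                                t_vector: Optional[np.ndarray] = None):
        """Per-class log joint density of data and root state.

        Returns ``(logjoint, weights)`` with ``logjoint`` of shape
        (n_classes, 61, n_patterns): log pi_s + log P(data below | root
        state s) under each site class, the quantity marginal ancestral
        reconstruction needs at the root of the working tree.
        """
        ts = t_vector if t_vector is not None else self._branch_lengths_vector(None)
        assignments, weights, scale = self._class_assignments_and_weights(params)
        fg_mask = np.array([n.foreground for n in self.branch_nodes])
        out = []
        logpi = np.log(np.maximum(self.pi, 1e-300))
        for w_bg, w_fg in assignments:
            omegas = np.where(fg_mask, w_fg, w_bg) if len(fg_mask) else np.array([])
            part, scl = self._root_partial_single(params.kappa, omegas, ts, scale)
            out.append(logpi[:, None] + np.log(np.maximum(part, 1e-300)) + scl[None, :])
        return np.array(out), weights

    # -- public likelihoods ------------------------------------------------
    def m0_loglike(self, kappa: float, omega: float,
                   branch_lengths: Optional[dict[str, float]] = None,
                   t_vector: Optional[np.ndarray] = None) -> float:
        ts = t_vector if t_vector is not None else self._branch_lengths_vector(branch_lengths)
        scale = self._eig(kappa, omega).mu
        if scale <= 0:
            scale = 1.0
        ll = self._pattern_loglikes_single(kappa, np.full(len(ts), omega), ts, scale)
        return float(self.counts @ ll)

    def class_pattern_loglikes(self, params: CodonModelParams,
                               t_vector: Optional[np.ndarray] = None
                               ) -> tuple[np.ndarray, np.ndarray]:
        """(4, npatterns) per-class log-likelihoods and the class weights."""
        ts = t_vector if t_vector is not None else self._branch_lengths_vector(None)
        assignments, weights, scale = self._class_assignments_and_weights(params)
        fg_mask = np.array([n.foreground for n in self.branch_nodes])
        w0 = params.omega0
        w2 = params.omega2 if params.omega2 is not None else 1.0
        if self._single_fg:
            lls = self._class_loglikes_fast(params.kappa, w0, w2, ts, scale, fg_mask)
        else:
            lls = []
            for w_bg, w_fg in assignments:
                omegas = np.where(fg_mask, w_fg, w_bg)
                lls.append(self._pattern_loglikes_single(params.kappa, omegas, ts, scale))
            lls = np.array(lls)
        return np.asarray(lls), weights

    def _class_loglikes_fast(self, kappa: float, w0: float, w2: float,
                             ts: np.ndarray, scale: float,
                             fg_mask: np.ndarray) -> np.ndarray:
        """Single-foreground fast path sharing background prunings across classes."""
        fg_idx = int(np.flatnonzero(fg_mask)[0])
        fg_node = self.branch_nodes[fg_idx]
        root = self.tree.root
        assert fg_node.parent is root or root.parent is None
        npat = self.patterns.shape[1]
        eigs = {w: self._eig(kappa, w) for w in {w0, 1.0, w2}}
        out = np.empty((4, npat))
        class_defs = ((w0, w0), (1.0, 1.0), (w0, w2), (1.0, w2))
        cache: dict[float, tuple] = {}
        for w_bg in (w0, 1.0):
            P_for = {}
            Ps = eigs[w_bg].transition_matrices(ts, scale)
            for node, P in zip(self.branch_nodes, Ps):
                P_for[node.id] = P
            # product over root children other than the fg child
            other = np.ones((61, npat))
            oscale = np.zeros(npat)
            for child in root.children:
                if child is fg_node:
                    continue
                contrib, s = self._propagate(child, P_for)
                other = other * contrib
                oscale = oscale + s
            if fg_node.is_tip:
                below, bscale = None, 0.0
            else:
                below, bscale = self._partial(fg_node, P_for)
            cache[w_bg] = (other, oscale, below, bscale)
        tfg = np.array([ts[fg_idx]])
        for k, (w_bg, w_fg) in enumerate(class_defs):
            other, oscale, below, bscale = cache[w_bg]
            Pfg = eigs[w_fg].transition_matrices(tfg, scale)[0]
            if below is None:
                contrib = Pfg[:, self._tip_codes[fg_node.label]]
                sscale = oscale
            else:
                contrib = Pfg @ below
                sscale = oscale + bscale
            site = self.pi @ (other * contrib)
            out[k] = np.log(np.maximum(site, 1e-300)) + sscale
        return out

    def branch_site_loglike(self, params: CodonModelParams,
                            t_vector: Optional[np.ndarray] = None) -> float:
        lls, weights = self.class_pattern_loglikes(params, t_vector)
        keep = weights > 0
        site_ll = logsumexp(lls[keep] + np.log(weights[keep])[:, None], axis=0)
        return float(self.counts @ site_ll)


def tree_log_likelihood(aln: CodonAlignment, tree: PhyloTree, spec: CodonModelSpec,
                        params: CodonModelParams,
                        code: GeneticCode | None = None) -> float:
    """Log-likelihood of the alignment on the tree under the given model."""
    engine = LikelihoodEngine(aln, tree, spec, code=code, pi=params.pi)
    if spec.model_family == "M0":
        return engine.m0_loglike(params.kappa, params.omega0)
    return engine.branch_site_loglike(params)


# ---------------------------------------------------------------------------
# fitting

def _softmax2(a0: float, a1: float) -> tuple[float, float]:
    z = 1.0 + math.exp(a0) + math.exp(a1)
    return math.exp(a0) / z, math.exp(a1) / z


def _pack_init(spec: CodonModelSpec, free_bl: bool, ts0: np.ndarray,
               rng: np.random.Generator, start: int) -> np.ndarray:
    # heuristic start, then seeded perturbations
    if spec.model_family == "M0":
        base = [math.log(2.0), math.log(0.4)]
    elif spec.model_family == "branch_site_null":
        base = [math.log(2.0), _logit(0.2), 1.0, -0.5]
    else:
        base = [math.log(2.0), _logit(0.2), 1.0, -0.5, math.log(1.0)]  # omega2 = 2
    x = np.array(base, dtype=float)
    if start > 0:
        x = x + rng.normal(0.0, 0.7, size=x.shape)
    if free_bl:
        tlog = np.log(np.maximum(ts0, 1e-4))
        if start > 0:
            tlog = tlog + rng.normal(0.0, 0.3, size=tlog.shape)
        x = np.concatenate([x, tlog])
    return x


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _unpack(spec: CodonModelSpec, x: np.ndarray, free_bl: bool, nbranch: int,
            pi: np.ndarray) -> tuple[CodonModelParams, Optional[np.ndarray]]:
    kappa = math.exp(min(x[0], 8.0))
    if spec.model_family == "M0":
        params = CodonModelParams(kappa=kappa, pi=pi, omega0=math.exp(min(x[1], 6.0)))
        k = 2
    else:
        omega0 = 1.0 / (1.0 + math.exp(-x[1]))
        p0, p1 = _softmax2(min(x[2], 30.0), min(x[3], 30.0))
        if spec.model_family == "branch_site_null":
            omega2 = 1.0
            k = 4
        else:
            omega2 = 1.0 + math.exp(min(x[4], 6.0))
            k = 5
        params = CodonModelParams(kappa=kappa, pi=pi, omega0=omega0, omega2=omega2,
                                  p0=p0, p1=p1)
    ts = np.exp(np.clip(x[k:], math.log(_MIN_T), math.log(50.0))) if free_bl else None
    return params, ts


def fit(aln: CodonAlignment, tree: PhyloTree, spec: CodonModelSpec,
        seed: int = 0, *, n_starts: int = 3,
        branch_lengths: Optional[dict[str, float]] = None,
        tol: float = 1e-8, max_iter: int = 500,
        code: GeneticCode | None = None,
        init_params: Optional[CodonModelParams] = None) -> ModelFit:
    """Maximum-likelihood fit by multi-start bounded quasi-Newton.

    Parameters are optimized on log/logit transforms; branch lengths are
    free unless ``branch_lengths`` pins them.  Starts are deterministic
    given ``seed``; the best log-likelihood wins, with the earliest start
    winning exact ties.
    """
    engine = LikelihoodEngine(aln, tree, spec, code=code)
    free_bl = branch_lengths is None
    nbranch = len(engine.branch_nodes)
    ts_fixed = None if free_bl else engine._branch_lengths_vector(branch_lengths)
    ts0 = engine._branch_lengths_vector(None)
    if free_bl and not np.any(ts0 > 0):
        ts0 = np.full(nbranch, 0.1)

    def objective(x: np.ndarray) -> float:
        try:
            params, ts = _unpack(spec, x, free_bl, nbranch, engine.pi)
        except (OverflowError, ValueError):
            return 1e10
        tvec = ts if free_bl else ts_fixed
        if spec.model_family == "M0":
            ll = engine.m0_loglike(params.kappa, params.omega0, t_vector=tvec)
        else:
            ll = engine.branch_site_loglike(params, t_vector=tvec)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    n_used = 0
    starts = []
    for s in range(n_starts):
        starts.append(_pack_init(spec, free_bl, ts0, rng, s))
    if init_params is not None:
        # a warm start replaces one cold start rather than adding to them
        starts = [_pack_from_params(spec, init_params, free_bl, ts0)] + starts[:-1]
    for s, x0 in enumerate(starts):
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"ftol": tol, "gtol": 1e-6,
                                         "maxiter": max_iter})
        n_used += 1
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    params, ts = _unpack(spec, best.x, free_bl, nbranch, engine.pi)
    tvec = ts if free_bl else ts_fixed
    bl = {lbl: float(t) for lbl, t in zip(engine.branch_labels, tvec)}
    lnL = -float(best.fun)
    converged = bool(best.success and np.isfinite(lnL))
    return ModelFit(spec=spec, params=params, branch_lengths=bl, lnL=lnL,
                    converged=converged, n_restarts_used=n_used,
                    aln=aln, tree=tree)


def _pack_from_params(spec: CodonModelSpec, p: CodonModelParams, free_bl: bool,
                      ts0: np.ndarray) -> np.ndarray:
    x = [math.log(p.kappa)]
    if spec.model_family == "M0":
        x.append(math.log(max(p.omega0, 1e-4)))
    else:
        w0 = min(max(p.omega0, 1e-4), 1 - 1e-4)
        x.append(_logit(w0))
        p0 = min(max(p.p0 if p.p0 is not None else 0.6, 1e-4), 1 - 1e-4)
        p1 = min(max(p.p1 if p.p1 is not None else 0.3, 1e-4), 1 - 1e-4)
        p2 = max(1.0 - p0 - p1, 1e-4)
        x.extend([math.log(p0 / p2), math.log(p1 / p2)])
        if spec.model_family == "branch_site_alt":
            w2 = p.omega2 if p.omega2 is not None else 2.0
            x.append(math.log(max(w2 - 1.0, 1e-3)))
    if free_bl:
        x.extend(np.log(np.maximum(ts0, 1e-4)))
    return np.array(x, dtype=float)


# ---------------------------------------------------------------------------
# likelihood-ratio tests

def null_distribution_p(stat: float, convention: str = "chi2_df1") -> float:
    """Tail probability of the branch-site LRT statistic.

    ``chi2_df1`` is the conservative chi-square(1) convention; ``mixture``
    is the 50:50 point-mass/chi-square(1) boundary mixture.
    """
    if stat <= 0:
        return 1.0
    p = float(chi2_dist.sf(stat, df=1))
    if convention == "mixture":
        return 0.5 * p
    if convention != "chi2_df1":
        raise ValueError(f"unknown convention {convention!r}")
    return p


def branch_site_lrt(aln: CodonAlignment, tree: PhyloTree,
                    foreground_branch: int | str | Sequence[int | str],
                    seed: int = 0, *,
                    frequency_mode: str = "F3x4",
                    branch_lengths: Optional[dict[str, float]] = None,
                    m0_fit: Optional[ModelFit] = None,
                    n_starts: int = 2, tol: float = 1e-8,
                    convention: str = "chi2_df1",
                    code: GeneticCode | None = None) -> LRTResult:
    """Branch-site test of positive selection on one foreground branch.

    Fits the Model A alternative (omega2 >= 1 estimated) and null
    (omega2 = 1) on the tree with the given branch marked foreground;
    the statistic 2(lnL_alt - lnL_null), clipped at zero, is referred to
    chi-square with one degree of freedom.  ``foreground_branch`` may be a
    single branch or a set of branches (e.g. a daughter-gene clade) marked
    jointly.  Branch lengths are estimated once under M0 and shared by
    both constrained fits unless supplied.
    """
    fg_keys = (list(foreground_branch)
               if isinstance(foreground_branch, (list, tuple, set))
               else [foreground_branch])
    work = tree.with_foreground(*fg_keys)
    fg_label = ",".join(str(work.find(k).label) for k in fg_keys)
    if branch_lengths is None:
        if m0_fit is None:
            # the input tree's branch lengths seed the M0 fit, which is
            # smooth and low-dimensional; one start suffices here
            m0_fit = fit(aln, tree, CodonModelSpec("M0", frequency_mode),
                         seed=seed, n_starts=max(1, n_starts - 1), tol=tol, code=code)
        branch_lengths = m0_fit.branch_lengths
    null_spec = CodonModelSpec("branch_site_null", frequency_mode)
    alt_spec = CodonModelSpec("branch_site_alt", frequency_mode)
    fit_null = fit(aln, work, null_spec, seed=seed, n_starts=max(1, n_starts - 1),
                   branch_lengths=branch_lengths, tol=tol, code=code)
    alt_init = replace(fit_null.params, omega2=2.0)
    fit_alt = fit(aln, work, alt_spec, seed=seed + 1, n_starts=n_starts,
                  branch_lengths=branch_lengths, tol=tol, code=code,
                  init_params=alt_init)
    stat = max(0.0, 2.0 * (fit_alt.lnL - fit_null.lnL))
    p = null_distribution_p(stat, convention)
    return LRTResult(foreground_branch=fg_label, stat=stat, df=1, p_raw=p,
                     lnL_alt=fit_alt.lnL, lnL_null=fit_null.lnL,
                     converged=fit_alt.converged and fit_null.converged,
                     fit_alt=fit_alt, fit_null=fit_null)


def edge_split_keys(tree: PhyloTree) -> dict[int, str]:
    """Canonical split-based key for each branch, mapped by child-node id.

    An edge is named by the smaller side of the tip bipartition it
    induces (ties broken lexicographically), e.g. ``"A"`` for a tip branch
    or ``"A,B"`` for the branch subtending tips A and B.  The key is
    invariant to root placement.
    """
    all_tips = frozenset(tree.tip_names())
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    keys = {}
    for node in tree.branches():
        side = below[id(node)]
        small = min((side, all_tips - side), key=lambda s: (len(s), tuple(sorted(s))))
        keys[node.id] = ",".join(sorted(small))
    return keys


def scan_branches(aln: CodonAlignment, tree: PhyloTree,
                  branch_set: Sequence[int | str], seed: int = 0,
                  **kwargs) -> list[LRTResult]:
    """One branch-site LRT per branch, Holm-Bonferroni adjusted jointly.

    The M0 branch-length fit is shared across the scan.  Results are
    returned in the order of ``branch_set``; failures on one branch are
    reported as unconverged results without aborting the scan.
    """
    if not branch_set:
        raise ValueError("branch_set must be non-empty")
    frequency_mode = kwargs.get("frequency_mode", "F3x4")
    m0_fit = kwargs.pop("m0_fit", None)
    if m0_fit is None and "branch_lengths" not in kwargs:
        m0_fit = fit(aln, tree, CodonModelSpec("M0", frequency_mode), seed=seed,
                     n_starts=max(2, kwargs.get("n_starts", 2)),
                     code=kwargs.get("code"))
    results = []
    for i, branch in enumerate(branch_set):
        try:
            res = branch_site_lrt(aln, tree, branch, seed=seed + 101 * i,
                                  m0_fit=m0_fit, **kwargs)
        except Exception:
            res = LRTResult(foreground_branch=str(branch), stat=0.0, df=1,
                            p_raw=1.0, converged=False)
        results.append(res)
    adjusted = holm_bonferroni([r.p_raw for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = p_adj
    return results


def holm_bonferroni(pvals: Sequence[float]) -> list[float]:
    """Holm's step-down adjustment: monotone, >= raw, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj.tolist()


def site_class_posteriors(fit_result: ModelFit,
                          threshold: float = 0.95):
    """Per-site posterior probabilities of the branch-site classes.

    Naive empirical Bayes at the maximum-likelihood estimates: for each
    site, P(class c | data) proportional to p_c L_c(site).  Returns a
    pandas DataFrame indexed by 1-based codon position with one column per
    class, the summed selected-class posterior, and a flag at
    ``threshold``.  Sites dropped from the likelihood (gap columns) carry
    NaN rows.
    """
    import pandas as pd

    if fit_result.spec.model_family != "branch_site_alt":
        raise ValueError("site-class posteriors require a branch-site alternative fit")
    if fit_result.aln is None or fit_result.tree is None:
        raise ValueError("fit does not carry its alignment and tree")
    engine = LikelihoodEngine(fit_result.aln, fit_result.tree, fit_result.spec,
                              pi=fit_result.params.pi)
    tvec = engine._branch_lengths_vector(fit_result.branch_lengths)
    lls, weights = engine.class_pattern_loglikes(fit_result.params, t_vector=tvec)
    logw = np.log(np.maximum(weights, 1e-300))
    joint = lls + logw[:, None]
    post = np.exp(joint - logsumexp(joint, axis=0, keepdims=True))  # (4, npat)
    n = fit_result.aln.n_codons
    table = np.full((n, 4), np.nan)
    for col, pat in zip(engine.kept_columns, engine.pattern_of_column):
        table[col] = post[:, pat]
    df = pd.DataFrame(table, columns=[f"class_{c}" for c in CLASS_NAMES],
                      index=pd.RangeIndex(1, n + 1, name="site"))
    df["p_selected"] = df["class_2a"] + df["class_2b"]
    df["selected"] = df["p_selected"] > threshold
    return df
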
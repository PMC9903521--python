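"""Codon substitution likelihood machinery for natural-selection tests.

Implements a GY94-style codon model over the 61 sense codons with F1X4
equilibrium frequencies: the rate of a single-nucleotide codon change i->j is
pi_j * kappa^[transition] * omega^[nonsynonymous]; multi-nucleotide changes
have rate 0. The matrix is scaled to one expected substitution per codon
site per unit branch length, so branch lengths are in substitutions per
codon.

On top of the rate matrix sit Felsenstein-pruning log-likelihoods on labeled
trees, maximum-likelihood fits of branch models (one shared omega, or one
omega per branch-label group) and of the 4-class branch-site model
("Model A": conserved, neutral, and two classes with foreground omega2 >= 1)
with its omega2 = 1 null, naive empirical Bayes site posteriors for the
positively selected classes, and chi-square likelihood-ratio tests between
nested fits.

Branch lengths are taken from the input tree and held fixed during fitting
(joint optimization available via ``optimize_branch_lengths``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from ._codons import (
    CODON_INDEX,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
)
from .io import LabeledTree

logger = logging.getLogger("panretain")

N_STATES = 61

KAPPA_BOUNDS = (0.1, 20.0)
OMEGA_BOUNDS = (1e-4, 50.0)
DEFAULT_RESTARTS = 5


# ---------------------------------------------------------------------------
# Model parameter containers
# ---------------------------------------------------------------------------

@dataclass
class CodonModelParams:
    """Parameters of a branch model: one omega per branch-label group."""

    kappa: float
    omega_by_label: dict[int, float]
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (N_STATES,) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be 61 frequencies summing to 1")
        if self.kappa < 0 or any(w < 0 for w in self.omega_by_label.values()):
            raise ValueError("rates must be non-negative")


@dataclass
class SiteClassMix:
    """Branch-site Model A mixture: classes 0 (omega0 everywhere), 1
    (neutral everywhere), 2a (background omega0, foreground omega2) and 2b
    (background 1, foreground omega2), with p2a/p2b = p0/p1."""

    p0: float
    p1: float
    p2a: float
    p2b: float
    omega0: float
    omega2: float
    kappa: float
    pi: np.ndarray
    omega1: float = 1.0

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])

    @classmethod
    def from_thetas(cls, theta1, theta2, omega0, omega2, kappa, pi):
        """(theta1, theta2) -> proportions: theta1 = p0+p1, theta2 = p0/(p0+p1);
        this parametrisation enforces p2a/p2b = p0/p1 automatically."""
        return cls(
            p0=theta1 * theta2,
            p1=theta1 * (1 - theta2),
            p2a=(1 - theta1) * theta2,
            p2b=(1 - theta1) * (1 - theta2),
            omega0=omega0,
            omega2=omega2,
            kappa=kappa,
            pi=pi,
        )


@dataclass
class FitResult:
    lnL: float
    np: int
    estimates: "CodonModelParams | SiteClassMix"
    converged: bool
    flat_likelihood: bool = False


@dataclass
class LrtResult:
    stat: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# Frequencies and rate matrix
# ---------------------------------------------------------------------------

def f1x4_frequencies(cds_sequences) -> np.ndarray:
    """F1X4 codon frequencies: pooled nucleotide frequencies over all three
    codon positions, codon frequency = product over positions, stop codons
    removed and the remainder renormalised."""
    counts = dict.fromkeys(NUCLEOTIDES, 0)
    seqs = cds_sequences.values() if isinstance(cds_sequences, dict) else cds_sequences
    for seq in seqs:
        for ch in seq.upper():
            if ch in counts:
                counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no A/C/G/T characters in input")
    nt_freq = {nt: counts[nt] / total for nt in NUCLEOTIDES}
    pi = np.array(
        [nt_freq[c[0]] * nt_freq[c[1]] * nt_freq[c[2]] for c in SENSE_CODONS]
    )
    s = pi.sum()
    if s == 0:
        raise ValueError("degenerate nucleotide composition")
    # floor zero frequencies so the rate matrix stays irreducible even for
    # compositions missing a nucleotide entirely
    pi = np.maximum(pi / s, 1e-10)
    return pi / pi.sum()


def _change_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(is_transition, is_nonsynonymous) boolean 61x61 tables for
    single-nucleotide codon changes; False/False rows elsewhere."""
    ts = np.zeros((N_STATES, N_STATES), dtype=bool)
    nonsyn = np.zeros((N_STATES, N_STATES), dtype=bool)
    single = np.zeros((N_STATES, N_STATES), dtype=bool)
    from ._codons import GENETIC_CODE

    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            single[i, j] = True
            ts[i, j] = is_transition(ci[p], cj[p])
            nonsyn[i, j] = GENETIC_CODE[ci] != GENETIC_CODE[cj]
    return single, ts, nonsyn


_SINGLE, _TS, _NONSYN = _change_tables()


def _build_q_unscaled(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    q = np.where(_SINGLE, pi[None, :], 0.0)
    q = q * np.where(_TS, kappa, 1.0) * np.where(_NONSYN, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def expected_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time of the unscaled Q."""
    q = _build_q_unscaled(kappa, omega, pi)
    return -float(np.dot(pi, np.diag(q)))


def build_q(
    kappa: float, omega: float, pi: np.ndarray, scale: float | None = None
) -> np.ndarray:
    """GY94 rate matrix: q_ij = pi_j * kappa^[transition] *
    omega^[nonsynonymous] for single-nucleotide changes, 0 otherwise; the
    diagonal closes the rows to 0.

    By default the matrix is divided by its own expected rate
    -sum_i pi_i q_ii so a branch of length t expects t substitutions per
    codon. Mixture models pass an explicit shared ``scale`` instead, so that
    site classes with larger omega genuinely evolve faster than conserved
    classes on the same branch.
    """
    q = _build_q_unscaled(kappa, omega, np.asarray(pi, dtype=float))
    if scale is None:
        scale = -float(np.dot(pi, np.diag(q)))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero expected rate)")
    return q / scale


class TransitionCache:
    """Eigendecomposition of a Q (reversible, so symmetrisable by sqrt(pi))
    giving P(t) = A exp(lambda t / scale) A^-1 cheaply for many t."""

    def __init__(
        self, kappa: float, omega: float, pi: np.ndarray, scale: float | None = None
    ):
        q = _build_q_unscaled(kappa, omega, pi)
        if scale is None:
            scale = -float(np.dot(pi, np.diag(q)))
        if scale <= 0:
            raise ValueError("degenerate rate matrix (zero expected rate)")
        sqrt_pi = np.sqrt(pi)
        sym = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        self._lam = lam / scale
        self._left = u.T * sqrt_pi[None, :]
        self._right = u / sqrt_pi[:, None]

    def p_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        p = (self._right * np.exp(self._lam * t)[None, :]) @ self._left
        return np.clip(p, 0.0, None)


def model_a_caches(mix: SiteClassMix) -> dict[tuple[str, int], TransitionCache]:
    """Transition caches for Model A, keyed by (branch type, site class).

    Within each branch type (background/foreground) all four class matrices
    share one scale factor — the mixture-weighted expected rate on that
    branch type — so branch lengths are expected substitutions per codon
    averaged over site classes, and classes with larger omega evolve
    proportionally faster. The same caches drive both the pruning likelihood
    and the simulator, keeping the two exactly consistent.
    """
    k, pi = mix.kappa, mix.pi
    omega_of = {
        ("bg", 0): mix.omega0, ("bg", 1): mix.omega1,
        ("bg", 2): mix.omega0, ("bg", 3): mix.omega1,
        ("fg", 0): mix.omega0, ("fg", 1): mix.omega1,
        ("fg", 2): mix.omega2, ("fg", 3): mix.omega2,
    }
    props = mix.proportions
    rates = {w: expected_rate(k, w, pi) for w in set(omega_of.values())}
    caches: dict[tuple[str, int], TransitionCache] = {}
    for btype in ("bg", "fg"):
        scale = sum(props[c] * rates[omega_of[(btype, c)]] for c in range(4))
        by_omega: dict[float, TransitionCache] = {}
        for c in range(4):
            w = omega_of[(btype, c)]
            if w not in by_omega:
                by_omega[w] = TransitionCache(k, w, pi, scale=scale)
            caches[(btype, c)] = by_omega[w]
    return caches


# ---------------------------------------------------------------------------
# Tree flattening
# ---------------------------------------------------------------------------

@dataclass
class _FlatTree:
    tip_names: list[str]
    postorder: list[int]          # internal nodes in postorder (root last)
    children: dict[int, list[int]]
    blen: np.ndarray              # branch length above each node
    bclass: np.ndarray            # branch label above each node
    root: int
    n_nodes: int


def flatten_tree(lt: LabeledTree) -> _FlatTree:
    nodes = list(lt.tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    tip_names, children = [], {}
    blen = np.zeros(len(nodes))
    bclass = np.zeros(len(nodes), dtype=int)
    postorder = []
    for node in lt.tree.postorder_node_iter():
        i = index[id(node)]
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ValueError("unlabeled tip in tree")
            tip_names.append((i, node.taxon.label))
        else:
            children[i] = [index[id(c)] for c in node.child_nodes()]
            postorder.append(i)
        if node.parent_node is not None:
            if node.edge.length is None:
                raise ValueError(f"missing branch length above node {i}")
            blen[i] = float(node.edge.length)
            bclass[i] = getattr(node.edge, "branch_class", 0)
    root = index[id(lt.tree.seed_node)]
    return _FlatTree(
        tip_names=[name for _, name in sorted(tip_names)],
        postorder=postorder,
        children=children,
        blen=blen,
        bclass=bclass,
        root=root,
        n_nodes=len(nodes),
    )


# ---------------------------------------------------------------------------
# Alignment encoding
# ---------------------------------------------------------------------------

def encode_alignment(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode aligned CDS into a (n_seqs, n_codons) int matrix; -1 marks a
    gap codon (treated as missing data in the likelihood)."""
    names = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    (length,) = lengths
    if length == 0:
        raise ValueError("zero-length alignment")
    if length % 3:
        raise ValueError("alignment length not divisible by 3")
    n_codons = length // 3
    codes = np.empty((len(names), n_codons), dtype=int)
    for r, name in enumerate(names):
        seq = alignment[name].upper()
        for k in range(n_codons):
            codon = seq[3 * k : 3 * k + 3]
            if codon == "---":
                codes[r, k] = -1
            elif codon in CODON_INDEX:
                codes[r, k] = CODON_INDEX[codon]
            elif codon in STOP_CODONS:
                raise ValueError(f"stop codon in {name!r} at codon {k + 1}")
            else:
                codes[r, k] = -1  # ambiguous -> missing
    return names, codes


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

class TreeLikelihood:
    """Felsenstein pruning on a labeled tree for GY94-family models.

    Precomputes tip partials once; each call supplies per-branch-class
    transition-matrix caches. Per-site log-likelihood vectors are exposed so
    mixture models can reuse the machinery.
    """

    def __init__(self, alignment: dict[str, str], lt: LabeledTree):
        self.flat = flatten_tree(lt)
        names, codes = encode_alignment(alignment)
        tip_ids = [i for i in range(self.flat.n_nodes) if i not in self.flat.children]
        tip_label_by_id = {}
        nodes = list(lt.tree.preorder_node_iter())
        for i, node in enumerate(nodes):
            if node.is_leaf():
                tip_label_by_id[i] = node.taxon.label
        missing = set(tip_label_by_id.values()) - set(names)
        if missing:
            raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
        self.n_sites = codes.shape[1]
        self._partials0 = {}
        row_by_name = {n: r for r, n in enumerate(names)}
        for i in tip_ids:
            row = codes[row_by_name[tip_label_by_id[i]]]
            part = np.zeros((self.n_sites, N_STATES))
            known = row >= 0
            part[known, row[known]] = 1.0
            part[~known, :] = 1.0
            self._partials0[i] = part

    def site_loglik(
        self, caches_by_class: dict[int, TransitionCache], pi: np.ndarray
    ) -> np.ndarray:
        """Per-site log-likelihood under one branch-class -> omega regime."""
        flat = self.flat
        partials: dict[int, np.ndarray] = {}
        scale = np.zeros(self.n_sites)
        pmats = {
            i: caches_by_class[flat.bclass[i]].p_matrix(flat.blen[i])
            for i in range(flat.n_nodes)
            if i != flat.root
        }
        for node in flat.postorder:
            acc = np.ones((self.n_sites, N_STATES))
            for child in flat.children[node]:
                child_part = partials.pop(child, None)
                if child_part is None:
                    child_part = self._partials0[child]
                acc *= child_part @ pmats[child].T
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            scale += np.log(mx)
            partials[node] = acc / mx[:, None]
        root_part = partials[flat.root]
        site_lik = root_part @ pi
        return np.log(np.clip(site_lik, 1e-300, None)) + scale

    # -- branch models ------------------------------------------------------

    def loglik_branch(self, params: CodonModelParams) -> float:
        classes = set(self.flat.bclass[i] for i in range(self.flat.n_nodes)
                      if i != self.flat.root)
        caches = {}
        by_omega: dict[float, TransitionCache] = {}
        for cls in classes:
            w = params.omega_by_label.get(cls, params.omega_by_label.get(0))
            if w is None:
                raise ValueError(f"no omega for branch class {cls}")
            if w not in by_omega:
                by_omega[w] = TransitionCache(params.kappa, w, params.pi)
            caches[cls] = by_omega[w]
        return float(self.site_loglik(caches, params.pi).sum())

    # -- Model A mixture ----------------------------------------------------

    def _class_site_logliks(self, mix: SiteClassMix) -> np.ndarray:
        """(4, n_sites) per-class site log-likelihoods for Model A."""
        caches = model_a_caches(mix)
        classes = sorted(set(self.flat.bclass))
        regimes = [
            {c: caches[("fg" if c >= 1 else "bg", cls)] for c in classes}
            for cls in range(4)
        ]
        return np.stack([self.site_loglik(r, mix.pi) for r in regimes])

    def loglik_mix(self, mix: SiteClassMix) -> float:
        logf = self._class_site_logliks(mix)
        props = np.clip(mix.proportions, 1e-12, None)
        return float(logsumexp(logf + np.log(props)[:, None], axis=0).sum())

    def site_posteriors(self, mix: SiteClassMix) -> np.ndarray:
        """(n_sites, 4) naive empirical Bayes class posteriors."""
        logf = self._class_site_logliks(mix)
        props = np.clip(mix.proportions, 1e-12, None)
        logp = logf + np.log(props)[:, None]
        logp -= logsumexp(logp, axis=0)[None, :]
        return np.exp(logp).T


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _alignment_varies(alignment: dict[str, str]) -> bool:
    seqs = list(alignment.values())
    return any(s != seqs[0] for s in seqs[1:])


def _multistart(objective, x0, bounds, n_restarts, seed, maxiter=200,
                extra_starts=()):
    """L-BFGS-B from a deterministic start plus seeded random restarts;
    returns the best (x, fun, success)."""
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [np.asarray(x0, dtype=float)]
    starts += [np.clip(np.asarray(s, dtype=float), lo, hi) for s in extra_starts]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(lo + rng.random(len(bounds)) * (hi - lo))
    best = None
    for start in starts:
        res = optimize.minimize(
            objective, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    return best


def fit_branch_model(
    alignment: dict[str, str],
    lt: LabeledTree,
    ratio_spec: dict[int, str] | None = None,
    pi: np.ndarray | None = None,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    optimize_branch_lengths: bool = False,
) -> FitResult:
    """Maximum-likelihood branch model fit.

    ``ratio_spec`` maps branch labels to named omega groups; labels sharing a
    name share an omega. None means one-ratio (every label -> one group).
    Branch lengths from the tree are held fixed unless
    ``optimize_branch_lengths`` is set. Free parameters: kappa plus one omega
    per group (plus branch lengths when jointly optimized).
    """
    tl = TreeLikelihood(alignment, lt)
    if pi is None:
        pi = f1x4_frequencies(
            {k: v.replace("-", "") for k, v in alignment.items()}
        )
    labels = sorted({int(c) for c in tl.flat.bclass} )
    if ratio_spec is None:
        ratio_spec = {lab: "all" for lab in labels}
    groups = sorted(set(ratio_spec.values()))
    n_groups = len(groups)

    flat = tl.flat
    branch_ids = [i for i in range(flat.n_nodes) if i != flat.root]
    blen0 = flat.blen.copy()

    flat_likelihood = not _alignment_varies(alignment)

    def unpack(x):
        kappa = math.exp(x[0])
        omegas = {g: math.exp(x[1 + gi]) for gi, g in enumerate(groups)}
        omega_by_label = {lab: omegas[ratio_spec.get(lab, groups[0])] for lab in labels}
        return kappa, omega_by_label, x[1 + n_groups :]

    def objective(x):
        kappa, omega_by_label, bl = unpack(x)
        if optimize_branch_lengths:
            for bi, i in enumerate(branch_ids):
                flat.blen[i] = math.exp(bl[bi])
        try:
            return -tl.loglik_branch(CodonModelParams(kappa, omega_by_label, pi))
        except (ValueError, FloatingPointError):
            return 1e12

    x0 = [math.log(2.0)] + [math.log(0.3)] * n_groups
    bounds = [tuple(np.log(KAPPA_BOUNDS))] + [tuple(np.log(OMEGA_BOUNDS))] * n_groups
    if optimize_branch_lengths:
        x0 += [math.log(max(b, 1e-4)) for b in blen0[branch_ids]]
        bounds += [(math.log(1e-6), math.log(20.0))] * len(branch_ids)

    res = _multistart(objective, x0, bounds, n_restarts, seed)
    kappa, omega_by_label, bl = unpack(res.x)
    if optimize_branch_lengths:
        for bi, i in enumerate(branch_ids):
            flat.blen[i] = math.exp(bl[bi])
    else:
        flat.blen = blen0
    n_free = 1 + n_groups + (len(branch_ids) if optimize_branch_lengths else 0)
    return FitResult(
        lnL=-float(res.fun),
        np=n_free,
        estimates=CodonModelParams(kappa, omega_by_label, pi),
        converged=bool(res.success) and not flat_likelihood,
        flat_likelihood=flat_likelihood,
    )


def _fit_model_a_impl(
    alignment, lt, pi, fix_omega2, n_restarts, seed, extra_starts=()
) -> FitResult:
    tl = TreeLikelihood(alignment, lt)
    if pi is None:
        pi = f1x4_frequencies({k: v.replace("-", "") for k, v in alignment.items()})
    if not any(c >= 1 for c in tl.flat.bclass):
        raise ValueError("tree has no foreground branch (no #k label)")
    flat_likelihood = not _alignment_varies(alignment)

    free_w2 = fix_omega2 is None

    def unpack(x):
        kappa = math.exp(x[0])
        theta1, theta2 = x[1], x[2]
        omega0 = x[3]
        omega2 = x[4] if free_w2 else fix_omega2
        return SiteClassMix.from_thetas(theta1, theta2, omega0, omega2, kappa, pi)

    def objective(x):
        try:
            return -tl.loglik_mix(unpack(x))
        except (ValueError, FloatingPointError):
            return 1e12

    eps = 1e-4
    x0 = [math.log(2.0), 0.7, 0.7, 0.1] + ([2.0] if free_w2 else [])
    bounds = [tuple(np.log(KAPPA_BOUNDS)), (eps, 1 - eps), (eps, 1 - eps),
              (1e-4, 1.0)] + ([(1.0, OMEGA_BOUNDS[1])] if free_w2 else [])
    res = _multistart(objective, x0, bounds, n_restarts, seed, maxiter=300,
                      extra_starts=extra_starts)
    mix = unpack(res.x)
    return FitResult(
        lnL=-float(res.fun),
        np=(1 + 2 + 1 + (1 if free_w2 else 0)),
        estimates=mix,
        converged=bool(res.success) and not flat_likelihood,
        flat_likelihood=flat_likelihood,
    )


def fit_model_a(
    alignment: dict[str, str],
    lt: LabeledTree,
    pi: np.ndarray | None = None,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> FitResult:
    """Branch-site Model A fit (omega2 >= 1 free); np = 4 site-pattern
    parameters (kappa, two mixing proportions, omega0) plus omega2."""
    return _fit_model_a_impl(alignment, lt, pi, None, n_restarts, seed)


def fit_model_a_null(
    alignment: dict[str, str],
    lt: LabeledTree,
    pi: np.ndarray | None = None,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> FitResult:
    """Model A null: omega2 fixed at 1 (df = 1 against the alternative)."""
    return _fit_model_a_impl(alignment, lt, pi, 1.0, n_restarts, seed)


def model_a_lrt(
    alignment: dict[str, str],
    lt: LabeledTree,
    pi: np.ndarray | None = None,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> tuple[FitResult, FitResult, LrtResult]:
    """Fit Model A and its null and test them against each other.

    The null is fitted first and its solution seeds the alternative's
    optimizer (at the omega2 = 1 boundary), which guarantees the nesting
    inequality lnL_alt >= lnL_null up to optimizer tolerance. Returns
    (null fit, alternative fit, LRT at df = 1).
    """
    f0 = fit_model_a_null(alignment, lt, pi=pi, n_restarts=n_restarts, seed=seed)
    null_mix = f0.estimates
    warm = [
        math.log(null_mix.kappa),
        null_mix.p0 + null_mix.p1,
        null_mix.p0 / max(null_mix.p0 + null_mix.p1, 1e-12),
        null_mix.omega0,
        1.0,
    ]
    fa = _fit_model_a_impl(
        alignment, lt, pi, None, n_restarts, seed, extra_starts=[warm]
    )
    return f0, fa, lrt(f0.lnL, fa.lnL, 1)


def neb_site_posteriors(
    alignment: dict[str, str], lt: LabeledTree, fit: FitResult,
    threshold: float = 0.6,
) -> tuple[np.ndarray, list[int]]:
    """Naive empirical Bayes posterior of the positively selected classes
    (2a + 2b) per site, and the 1-based sites exceeding ``threshold``."""
    if not isinstance(fit.estimates, SiteClassMix):
        raise TypeError("fit is not a Model A fit")
    tl = TreeLikelihood(alignment, lt)
    post = tl.site_posteriors(fit.estimates)
    fg = post[:, 2] + post[:, 3]
    selected = [i + 1 for i in range(len(fg)) if fg[i] > threshold]
    return fg, selected


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------

def lrt(lnL0: float, lnL1: float, df: int) -> LrtResult:
    """Chi-square LRT of nested fits: stat = 2(lnL1 - lnL0).

    A slightly negative statistic (optimizer noise on equivalent fits) is
    clamped to 0 with a warning; a substantially negative one raises.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnL1 - lnL0)
    if stat < 0:
        if stat < -1e-3:
            raise ValueError(
                f"alternative lnL below null lnL (2*dl = {stat:.6g}): "
                "models not nested or optimization failed"
            )
        logger.warning("clamping slightly negative LRT statistic %.3g to 0", stat)
        stat = 0.0
    p = float(stats.chi2.sf(stat, df))
    return LrtResult(stat=stat, df=df, p_value=p)
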
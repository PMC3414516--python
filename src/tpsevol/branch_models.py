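"""GY94 codon model, pruning likelihood, branch-model fits and LRTs.

The Goldman-Yang (1994) codon substitution process assigns rate
``q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]`` to
single-nucleotide codon changes (zero for multi-hit changes), normalized
so branch lengths are expected substitutions per codon.  The one-ratio
model shares a single omega across the tree; the two-ratio model gives a
designated clade (all its internal edges plus the stem edge) its own
omega.  Twice the log-likelihood difference between the nested fits is
referred to a chi-square distribution with df equal to the extra
parameter count (here 1), exactly the branch-model LRT used to contrast
selective pressure between TPS gene clades.

The pruning (Felsenstein) recursion runs over site patterns with
per-node scaling; branch-length derivatives are computed analytically by
a pre-order pass, which keeps full-tree optimization fast enough for
simulation calibration studies.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._codons import (
    CODON_INDEX,
    N_SENSE,
    SENSE_CODONS,
    STEP_DST,
    STEP_IS_NONSYN,
    STEP_IS_TS,
    STEP_SRC,
)
from .core import CodonAlignment, mask_gapped_columns
from .errors import NotNestedError, TpsEvolError, TreeDataMismatchError
from .trees import PhyloTree

_NT_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

DEFAULT_BOUNDS = {
    "kappa": (1e-3, 100.0),
    "omega": (1e-6, 50.0),
    "t": (0.0, 50.0),
}


@dataclass
class CodonFrequencies:
    """Equilibrium codon frequencies over the 61 sense codons."""

    model: str  # equal | F1x4 | F3x4 | empirical_codon
    pi: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (N_SENSE,):
            raise TpsEvolError("pi must be a 61-vector over sense codons")
        if np.any(self.pi < 0):
            raise TpsEvolError("negative codon frequency")
        self.pi = self.pi / self.pi.sum()


def build_codon_freqs(
    ca: CodonAlignment, model: str = "F3x4", floor: float = 1e-6
) -> CodonFrequencies:
    """Estimate equilibrium codon frequencies from an alignment.

    F3x4 multiplies position-specific nucleotide frequencies over sense
    codons; F1x4 uses overall nucleotide frequencies; 'empirical_codon'
    uses observed codon proportions.  Zero-count categories are floored at
    ``floor`` and the vector renormalized.
    """
    if not ca.rows or ca.ncol == 0:
        raise TpsEvolError("empty alignment")
    cells = [
        c for row in ca.rows for c in row if c in CODON_INDEX
    ]
    if model == "equal":
        pi = np.full(N_SENSE, 1.0 / N_SENSE)
    elif model == "empirical_codon":
        counts = np.zeros(N_SENSE)
        for c in cells:
            counts[CODON_INDEX[c]] += 1
        pi = counts / counts.sum()
    elif model in ("F1x4", "F3x4"):
        pos_counts = np.zeros((3, 4))
        for c in cells:
            for p in range(3):
                pos_counts[p, _NT_IDX[c[p]]] += 1
        if model == "F1x4":
            tot = pos_counts.sum(axis=0)
            nt = tot / tot.sum()
            pos = np.tile(nt, (3, 1))
        else:
            pos = pos_counts / pos_counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                pos[0, _NT_IDX[c[0]]]
                * pos[1, _NT_IDX[c[1]]]
                * pos[2, _NT_IDX[c[2]]]
                for c in SENSE_CODONS
            ]
        )
    else:
        raise ValueError(f"unknown frequency model {model!r}")
    pi = np.maximum(pi, floor)
    return CodonFrequencies(model=model, pi=pi / pi.sum())


@dataclass
class RateMatrix:
    """Normalized GY94 generator (expected substitutions per codon = 1)."""

    Q: np.ndarray
    pi: np.ndarray
    kappa: float
    omega: float
    scale: float  # raw mean rate divided out


def gy94_rate_matrix(
    kappa: float, omega: float, freqs: CodonFrequencies
) -> RateMatrix:
    """Build the normalized GY94 instantaneous rate matrix.

    Off-diagonal rates are nonzero only for single-nucleotide changes
    between sense codons; the matrix satisfies detailed balance with pi
    and is scaled so -sum_i pi_i q_ii = 1.
    """
    if kappa < 0 or omega < 0:
        raise TpsEvolError("kappa and omega must be nonnegative")
    pi = freqs.pi
    Q = np.zeros((N_SENSE, N_SENSE))
    rates = pi[STEP_DST] * np.where(STEP_IS_TS, kappa, 1.0)
    rates = rates * np.where(STEP_IS_NONSYN, omega, 1.0)
    Q[STEP_SRC, STEP_DST] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    if mean_rate <= 1e-12:
        raise TpsEvolError(
            "degenerate rate matrix (frequency mass on one codon?)"
        )
    return RateMatrix(
        Q=Q / mean_rate, pi=pi, kappa=kappa, omega=omega, scale=mean_rate
    )


class SpectralQ:
    """Eigendecomposition of a reversible Q in the pi^1/2-symmetrized basis.

    Gives cheap P(t) = exp(Qt) and Q P(t) for many branch lengths from one
    decomposition.
    """

    def __init__(self, rm: RateMatrix):
        self.pi = rm.pi
        d = np.sqrt(rm.pi)
        S = (rm.Q * d[:, None]) / d[None, :]
        S = 0.5 * (S + S.T)  # symmetrize residual float noise
        lam, V = np.linalg.eigh(S)
        self.lam = lam
        self.left = V / d[:, None]  # diag(1/d) @ V
        self.right = V.T * d[None, :]  # V.T @ diag(d)

    def P(self, t: float) -> np.ndarray:
        if t < 0:
            raise TpsEvolError("negative branch length")
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P

    def P_and_QP(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        e = np.exp(self.lam * t)
        P = (self.left * e) @ self.right
        QP = (self.left * (self.lam * e)) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P, QP


def transition_matrix(rm: RateMatrix, t: float) -> np.ndarray:
    """Stochastic matrix exp(Qt); rows sum to 1, entries clipped at 0."""
    return SpectralQ(rm).P(t)


# =================================================================== engine

class _TreeIndex:
    """Postorder-indexed topology for the pruning recursion.

    Nodes are numbered in postorder (root last); every non-root node owns
    the edge to its parent, indexed by the node's own number.
    """

    def __init__(self, ptree: PhyloTree, leaf_ids: list[str]):
        t = ptree.derooted().tree
        nodes = list(t.postorder_node_iter())
        if len([n for n in nodes if n.is_leaf()]) < 3:
            raise TpsEvolError("need an unrooted tree with >= 3 leaves")
        self.n_nodes = len(nodes)
        self.node_of = {id(n): k for k, n in enumerate(nodes)}
        self.children: list[list[int]] = [[] for _ in nodes]
        self.parent = np.full(self.n_nodes, -1, dtype=np.intp)
        self.edge_length = np.zeros(self.n_nodes)
        self.leaf_row = np.full(self.n_nodes, -1, dtype=np.intp)
        self.leaf_sets: list[frozenset[str]] = [frozenset()] * self.n_nodes
        row_of = {name: r for r, name in enumerate(leaf_ids)}
        tree_leaves = set()
        for k, n in enumerate(nodes):
            if n.parent_node is not None:
                p = self.node_of[id(n.parent_node)]
                self.parent[k] = p
                self.edge_length[k] = n.edge.length or 0.0
            if n.is_leaf():
                label = n.taxon.label
                tree_leaves.add(label)
                if label not in row_of:
                    raise TreeDataMismatchError(
                        f"tree leaf {label!r} absent from alignment"
                    )
                self.leaf_row[k] = row_of[label]
                self.leaf_sets[k] = frozenset([label])
            else:
                kids = [self.node_of[id(c)] for c in n.child_nodes()]
                self.children[k] = kids
                self.leaf_sets[k] = frozenset().union(
                    *(self.leaf_sets[c] for c in kids)
                )
        if tree_leaves != set(leaf_ids):
            raise TreeDataMismatchError(
                "alignment ids not matched by tree leaves: "
                f"{sorted(set(leaf_ids) - tree_leaves)}"
            )
        self.root = self.n_nodes - 1
        self.edges = [k for k in range(self.n_nodes) if k != self.root]
        self.postorder_internal = [
            k for k in range(self.n_nodes) if self.children[k]
        ]

    def edge_classes(
        self, foreground_leaves: frozenset[str] | None
    ) -> np.ndarray:
        """0 = background, 1 = foreground (clade-internal edges + stem)."""
        cls = np.zeros(self.n_nodes, dtype=np.intp)
        if foreground_leaves:
            found_stem = False
            for k in self.edges:
                if self.leaf_sets[k] <= foreground_leaves:
                    cls[k] = 1
                    if self.leaf_sets[k] == foreground_leaves:
                        found_stem = True
            if not found_stem:
                raise TreeDataMismatchError(
                    "foreground clade is not a subtree in this orientation"
                )
        return cls


def _compress_patterns(ca: CodonAlignment, leaf_ids: list[str]):
    """(leaf x pattern) codon-index matrix (-1 = gap/ambiguous) + weights."""
    mat = np.full((len(leaf_ids), ca.ncol), -1, dtype=np.int16)
    for r, name in enumerate(leaf_ids):
        for c, cell in enumerate(ca.row(name)):
            mat[r, c] = CODON_INDEX.get(cell, -1)
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class PruningEngine:
    """Likelihood and branch-length gradient for one (tree, data) pair."""

    def __init__(self, ptree: PhyloTree, ca: CodonAlignment):
        self.leaf_ids = list(ca.ids)
        self.index = _TreeIndex(ptree, self.leaf_ids)
        self.patterns, self.weights = _compress_patterns(ca, self.leaf_ids)
        self.npat = self.patterns.shape[1]
        # one-hot leaf partials (gap -> all ones)
        self._leaf_partials = {}
        for k in range(self.index.n_nodes):
            r = self.index.leaf_row[k]
            if r >= 0:
                L = np.zeros((N_SENSE, self.npat))
                states = self.patterns[r]
                ok = states >= 0
                L[states[ok], np.nonzero(ok)[0]] = 1.0
                L[:, ~ok] = 1.0
                self._leaf_partials[k] = L

    # ---------------------------------------------------------- pruning
    def loglik(
        self,
        pi: np.ndarray,
        spectra: list[SpectralQ],
        edge_class: np.ndarray,
        t: np.ndarray,
        grad_t: bool = False,
    ):
        """Log-likelihood; optionally also d lnL / d t per edge.

        ``t`` is indexed by node number (root entry ignored).  Per-node
        rescaling guards underflow; the pre-order gradient pass carries
        its own log-scale so the ratio is exact.
        """
        idx = self.index
        nn = idx.n_nodes
        P = [None] * nn
        QP = [None] * nn
        for k in idx.edges:
            sq = spectra[edge_class[k]]
            if grad_t:
                P[k], QP[k] = sq.P_and_QP(t[k])
            else:
                P[k] = sq.P(t[k])
        Lhat = [None] * nn
        gscale = [None] * nn  # cumulative subtree log-scale per pattern
        PL = [None] * nn  # P_k @ Lhat_k for each non-root node
        for k in range(nn):
            if idx.leaf_row[k] >= 0:
                Lhat[k] = self._leaf_partials[k]
                gscale[k] = np.zeros(self.npat)
            else:
                prod = np.ones((N_SENSE, self.npat))
                g = np.zeros(self.npat)
                for c in idx.children[k]:
                    PL[c] = P[c] @ Lhat[c]
                    prod *= PL[c]
                    g += gscale[c]
                m = prod.max(axis=0)
                m = np.where(m > 0, m, 1.0)
                prod /= m
                Lhat[k] = prod
                gscale[k] = g + np.log(m)
        root = idx.root
        site = pi @ Lhat[root]
        if np.any(site <= 0):
            return (-np.inf, np.zeros(nn)) if grad_t else -np.inf
        logsite = np.log(site) + gscale[root]
        lnL = float(self.weights @ logsite)
        if not grad_t:
            return lnL

        # pre-order pass: Uhat_v with log-scale hscale_v
        Uhat = [None] * nn
        hscale = [None] * nn
        grad = np.zeros(nn)
        for k in range(nn - 1, -1, -1):
            if not idx.children[k]:
                continue
            for c in idx.children[k]:
                if k == root:
                    base = np.repeat(pi[:, None], self.npat, axis=1)
                    h = np.zeros(self.npat)
                else:
                    base = P[k].T @ Uhat[k]
                    h = hscale[k].copy()
                for s in idx.children[k]:
                    if s is c:
                        continue
                    base = base * PL[s]
                    h = h + gscale[s]
                m = base.max(axis=0)
                m = np.where(m > 0, m, 1.0)
                Uhat[c] = base / m
                hscale[c] = h + np.log(m)
                num = np.einsum(
                    "ip,ip->p", Uhat[c], QP[c] @ Lhat[c]
                )
                rel = np.exp(hscale[c] + gscale[c] - gscale[root])
                grad[c] = float(
                    self.weights @ (num * rel / site)
                )
        return lnL, grad


# ============================================================== model fits

@dataclass
class BranchModelFit:
    model: str  # one_ratio | two_ratio
    omega_by_class: dict[str, float]
    kappa: float
    freqs: CodonFrequencies
    branch_lengths: dict[tuple[str, ...], float]
    loglik: float
    n_free_params: int
    converged: bool
    iterations: int
    n_starts: int
    data_digest: str
    foreground: frozenset[str] | None = None
    tree_newick: str = ""
    warnings: list[str] = field(default_factory=list)


@dataclass
class LRTResult:
    lnL0: float
    lnL1: float
    statistic: float
    df: int
    p_value: float


def _data_digest(ptree: PhyloTree, ca: CodonAlignment) -> str:
    h = hashlib.sha256()
    for name, row in zip(ca.ids, ca.rows):
        h.update(name.encode())
        h.update("".join(row).encode())
    h.update(",".join(sorted(ptree.leaf_ids)).encode())
    # topology as sorted bipartitions so rerooting does not break nesting
    for bp in sorted(map(sorted, ptree.bipartition_sets())):
        h.update(";".join(bp).encode())
    return h.hexdigest()


def _resolve_foreground(ptree: PhyloTree, foreground) -> frozenset[str] | None:
    if foreground is None:
        return None
    if isinstance(foreground, str):
        return ptree.clade_leaf_set(foreground)
    return frozenset(foreground)


def pruning_loglik(
    tree: PhyloTree,
    ca: CodonAlignment,
    kappa: float,
    omega_by_class,
    freqs: CodonFrequencies,
    branch_lengths: dict | None = None,
    foreground=None,
    gap_policy: str = "complete_deletion",
) -> float:
    """Log-likelihood of a codon alignment under fixed GY94 parameters.

    ``omega_by_class`` is a single float (one class) or a (background,
    foreground) pair used with ``foreground``.  Branch lengths default to
    the tree's own; pass ``branch_lengths`` keyed by child-side leaf sets
    (as frozensets or sorted tuples) to override.
    """
    if gap_policy == "complete_deletion":
        ca = mask_gapped_columns(ca, "complete_deletion")
    engine = PruningEngine(tree, ca)
    fg = _resolve_foreground(tree, foreground)
    edge_class = engine.index.edge_classes(fg)
    omegas = (
        [float(omega_by_class)]
        if np.isscalar(omega_by_class)
        else [float(w) for w in omega_by_class]
    )
    spectra = [
        SpectralQ(gy94_rate_matrix(kappa, w, freqs)) for w in omegas
    ]
    t = engine.index.edge_length.copy()
    if branch_lengths is not None:
        for k in engine.index.edges:
            key = frozenset(engine.index.leaf_sets[k])
            if key in branch_lengths:
                t[k] = branch_lengths[key]
            else:
                tup = tuple(sorted(key))
                if tup in branch_lengths:
                    t[k] = branch_lengths[tup]
    return engine.loglik(freqs.pi, spectra, edge_class, t)


def fit_branch_model(
    tree: PhyloTree,
    ca: CodonAlignment,
    model: str = "one_ratio",
    foreground=None,
    freq_model: str = "F3x4",
    gap_policy: str = "complete_deletion",
    n_starts: int = 3,
    seed: int = 0,
    init: dict | None = None,
    class_labels: tuple[str, str] = ("background", "foreground"),
    maxiter: int = 1000,
) -> BranchModelFit:
    """Maximize the GY94 likelihood over kappa, omega(s) and branch lengths.

    ``model='two_ratio'`` requires ``foreground`` (a clade tag on the tree
    or an explicit leaf-id set); all edges inside that clade plus its stem
    edge share the foreground omega.  Multi-start bounded quasi-Newton
    (L-BFGS-B) with analytic branch-length gradients; ``init`` may supply
    warm-start values {'kappa', 'omegas', 't'} (t keyed like
    ``branch_lengths`` or a scalar).
    """
    if model not in ("one_ratio", "two_ratio"):
        raise ValueError(f"unknown model {model!r}")
    if model == "two_ratio" and foreground is None:
        raise TpsEvolError("two_ratio fit needs a foreground clade")
    if gap_policy == "complete_deletion":
        ca_fit = mask_gapped_columns(ca, "complete_deletion")
    else:
        ca_fit = ca
    freqs = build_codon_freqs(ca_fit, freq_model)
    engine = PruningEngine(tree, ca_fit)
    idx = engine.index
    fg = _resolve_foreground(tree, foreground) if model == "two_ratio" else None
    edge_class = idx.edge_classes(fg)
    n_omega = 2 if model == "two_ratio" else 1
    edges = idx.edges
    n_edges = len(edges)

    lo = np.empty(1 + n_omega + n_edges)
    hi = np.empty_like(lo)
    lo[0], hi[0] = DEFAULT_BOUNDS["kappa"]
    lo[1 : 1 + n_omega], hi[1 : 1 + n_omega] = DEFAULT_BOUNDS["omega"]
    lo[1 + n_omega :], hi[1 + n_omega :] = DEFAULT_BOUNDS["t"]

    def unpack(x):
        kappa = x[0]
        omegas = x[1 : 1 + n_omega]
        t = np.zeros(idx.n_nodes)
        t[edges] = x[1 + n_omega :]
        return kappa, omegas, t

    def value(x):
        kappa, omegas, t = unpack(x)
        spectra = [
            SpectralQ(gy94_rate_matrix(kappa, w, freqs)) for w in omegas
        ]
        return engine.loglik(freqs.pi, spectra, edge_class, t)

    def value_and_grad(x):
        kappa, omegas, t = unpack(x)
        spectra = [
            SpectralQ(gy94_rate_matrix(kappa, w, freqs)) for w in omegas
        ]
        lnL, gt = engine.loglik(
            freqs.pi, spectra, edge_class, t, grad_t=True
        )
        g = np.zeros_like(x)
        g[1 + n_omega :] = gt[edges]
        # forward differences for kappa and the omegas
        for p in range(1 + n_omega):
            h = 1e-5 * max(abs(x[p]), 1e-2)
            xp = x.copy()
            xp[p] = min(x[p] + h, hi[p])
            step = xp[p] - x[p]
            if step <= 0:
                xp[p] = x[p] - h
                step = xp[p] - x[p]
            g[p] = (value(xp) - lnL) / step
        return -lnL, -g

    rng = np.random.default_rng(seed)
    x0_base = np.empty(1 + n_omega + n_edges)
    x0_base[0] = 2.0
    x0_base[1 : 1 + n_omega] = 0.2
    x0_base[1 + n_omega :] = 0.1
    if init:
        if "kappa" in init:
            x0_base[0] = init["kappa"]
        if "omegas" in init:
            om = np.atleast_1d(np.asarray(init["omegas"], dtype=float))
            x0_base[1 : 1 + n_omega] = (
                om if om.size == n_omega else om[0]
            )
        if "t" in init:
            tv = init["t"]
            if np.isscalar(tv):
                x0_base[1 + n_omega :] = tv
            else:
                for i, k in enumerate(edges):
                    key = frozenset(idx.leaf_sets[k])
                    if key in tv:
                        x0_base[1 + n_omega + i] = tv[key]
    x0_base = np.clip(x0_base, lo + 1e-9, hi)

    best = None
    total_iters = 0
    for s in range(max(1, n_starts)):
        if s == 0:
            x0 = x0_base
        else:
            x0 = np.clip(
                x0_base * np.exp(rng.normal(0.0, 0.3, x0_base.size)),
                lo + 1e-9,
                hi,
            )
        res = optimize.minimize(
            value_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        total_iters += int(res.nit)
        if best is None or res.fun < best.fun:
            best = res

    kappa, omegas, t = unpack(best.x)
    labels = (
        ("all",) if model == "one_ratio" else class_labels
    )
    branch_lengths = {
        tuple(sorted(idx.leaf_sets[k])): float(t[k]) for k in edges
    }
    return BranchModelFit(
        model=model,
        omega_by_class={lab: float(w) for lab, w in zip(labels, omegas)},
        kappa=float(kappa),
        freqs=freqs,
        branch_lengths=branch_lengths,
        loglik=-float(best.fun),
        n_free_params=1 + n_omega + n_edges,
        converged=bool(best.success),
        iterations=total_iters,
        n_starts=max(1, n_starts),
        data_digest=_data_digest(tree, ca_fit),
        foreground=fg,
        tree_newick=tree.to_newick(),
        warnings=[] if best.success else [str(best.message)],
    )


def likelihood_ratio_test(
    fit0: BranchModelFit, fit1: BranchModelFit
) -> LRTResult:
    """Chi-square LRT of nested branch-model fits.

    Verifies same data/topology by digest; the statistic is clipped at 0
    when the alternative's optimum lands marginally below the null's
    (optimizer noise).
    """
    if fit0.data_digest != fit1.data_digest:
        raise NotNestedError("fits computed on different data or trees")
    df = fit1.n_free_params - fit0.n_free_params
    if df < 1:
        raise NotNestedError("alternative has no extra parameters")
    stat = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    return LRTResult(
        lnL0=fit0.loglik,
        lnL1=fit1.loglik,
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
    )


def run_table1_suite(
    ca: CodonAlignment,
    trees: list[dict],
    partition=None,
    regions: tuple[str, ...] = ("full_length", "TPS", "TPP"),
    freq_model: str = "F3x4",
    gap_policy: str = "complete_deletion",
    n_starts: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """One-ratio vs two-ratio LRT for each (tree, region) combination.

    ``trees`` entries are dicts with keys ``name``, ``tree`` (PhyloTree),
    ``foreground`` (clade tag or leaf set) and optional ``ids`` (sequence
    subset refit on the pruned tree).  The two-ratio fit is warm-started
    from the one-ratio optimum, which both speeds convergence and
    guarantees a nonnegative LRT statistic.  Returns a long-format table
    (tree, region, model, parameters, lnL, 2dl, p) that mirrors the
    branch-model summary layout; the frequency model and gap policy used
    are embedded in every row because log-likelihoods are only comparable
    within one setting.
    """
    rows = []
    for spec_i, entry in enumerate(trees):
        name = entry.get("name", f"tree{spec_i + 1}")
        tree: PhyloTree = entry["tree"]
        foreground = entry.get("foreground")
        ids = entry.get("ids")
        sub_ca = ca.subset_rows(ids) if ids else ca
        sub_tree = tree.subtree_for_leaves(sub_ca.ids) if ids else tree
        for region in regions:
            if region == "full_length" or partition is None:
                reg_ca = sub_ca
            else:
                reg_ca = sub_ca.subset_columns(
                    sorted(partition.domains[region])
                )
            fit0 = fit_branch_model(
                sub_tree,
                reg_ca,
                model="one_ratio",
                freq_model=freq_model,
                gap_policy=gap_policy,
                n_starts=n_starts,
                seed=seed,
            )
            fit1 = fit_branch_model(
                sub_tree,
                reg_ca,
                model="two_ratio",
                foreground=foreground,
                freq_model=freq_model,
                gap_policy=gap_policy,
                n_starts=n_starts,
                seed=seed,
                init={
                    "kappa": fit0.kappa,
                    "omegas": [fit0.omega_by_class["all"]] * 2,
                    "t": {
                        frozenset(k): v
                        for k, v in fit0.branch_lengths.items()
                    },
                },
            )
            lrt = likelihood_ratio_test(fit0, fit1)
            common = {
                "tree": name,
                "region": region,
                "freq_model": freq_model,
                "gap_policy": gap_policy,
            }
            rows.append(
                {
                    **common,
                    "model": "one_ratio",
                    "parameters": f"omega={fit0.omega_by_class['all']:.5f}",
                    "lnL": fit0.loglik,
                    "2dl": np.nan,
                    "p": np.nan,
                }
            )
            om = fit1.omega_by_class
            rows.append(
                {
                    **common,
                    "model": "two_ratio",
                    "parameters": (
                        f"omega_bg={om['background']:.5f}, "
                        f"omega_fg={om['foreground']:.5f}, "
                    ),
                    "lnL": fit1.loglik,
                    "2dl": lrt.statistic,
                    "p": lrt.p_value,
                }
            )
    return pd.DataFrame(rows)
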
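"""Family-level evolution: trees, duplicates, ancestral lineages, fates.

Covers the tree-based half of the analysis: JTT maximum-likelihood
pairwise protein distances, neighbor-joining with bootstrap support,
same-species cherry detection (the operational definition of a recently
duplicated gene pair), minimum ancestral-gene counting at the
monocot-dicot split, tandem/segmental duplication-mechanism calls from
coordinates and paralogous-block tables, and duplicate-gene fate
classification from expression presence/absence matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

from ._jtt import JTT_AA_ORDER, JTT_EXCHANGEABILITIES, JTT_FREQS
from .core import ExpressionMatrix, ProteinAlignment
from .errors import TpsEvolError, TreeDataMismatchError
from .trees import PhyloTree

_AA_IDX = {a: i for i, a in enumerate(JTT_AA_ORDER)}

MECHANISMS = ("tandem", "segmental", "whole_genome_block", "unknown")
FATES = (
    "shared_expression",
    "nonfunctionalization_candidate",
    "subfunctionalization_candidate",
    "divergent",
    "unknown",
)

DEFAULT_TANDEM_DISTANCE = 100_000  # bp between gene spans


@dataclass
class DuplicatePair:
    gene_a: str
    gene_b: str
    species: str
    mechanism: str = "unknown"
    fate: str = "unknown"


# ------------------------------------------------------------ JTT distance

class _JTTSpectral:
    """Normalized JTT rate matrix with cached eigendecomposition."""

    def __init__(self):
        pi = JTT_FREQS / JTT_FREQS.sum()
        Q = JTT_EXCHANGEABILITIES * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        Q /= -float(pi @ np.diag(Q))
        d = np.sqrt(pi)
        S = (Q * d[:, None]) / d[None, :]
        S = 0.5 * (S + S.T)
        lam, V = np.linalg.eigh(S)
        self.pi = pi
        self.lam = lam
        self.left = V / d[:, None]
        self.right = V.T * d[None, :]

    def P(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.lam * t)) @ self.right
        return np.clip(P, 1e-300, None)


_JTT = None


def _jtt() -> _JTTSpectral:
    global _JTT
    if _JTT is None:
        _JTT = _JTTSpectral()
    return _JTT


MAX_JTT_DISTANCE = 10.0


def jtt_distance(seq_i: str, seq_j: str) -> float:
    """ML distance (substitutions/site) between two gapped protein rows.

    Maximizes sum(log pi_a P_ab(t)) over t >= 0 under the JTT model on the
    columns where both rows are ungapped; capped at 10 substitutions/site.
    """
    pairs = [
        (_AA_IDX[a], _AA_IDX[b])
        for a, b in zip(seq_i.upper(), seq_j.upper())
        if a in _AA_IDX and b in _AA_IDX
    ]
    if not pairs:
        raise TpsEvolError("no comparable (both-ungapped) columns")
    ai = np.asarray([p[0] for p in pairs])
    bi = np.asarray([p[1] for p in pairs])
    if np.all(ai == bi):
        return 0.0
    model = _jtt()

    def nll(t):
        return -float(np.log(model.P(t)[ai, bi]).sum())

    res = optimize.minimize_scalar(
        nll, bounds=(1e-8, MAX_JTT_DISTANCE), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(min(res.x, MAX_JTT_DISTANCE))


def jtt_distance_matrix(pa: ProteinAlignment) -> np.ndarray:
    n = len(pa.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jtt_distance(pa.rows[i], pa.rows[j])
    return d


# --------------------------------------------------------------------- NJ

def nj_tree(d: np.ndarray, ids: list[str]) -> PhyloTree:
    """Neighbor-joining on a symmetric distance matrix.

    Deterministic: ties in the Q-criterion break toward the lowest index
    pair.  Negative branch-length estimates are floored at zero.  Returns
    an unrooted tree (trifurcating seed node).
    """
    d = np.asarray(d, dtype=float)
    n = len(ids)
    if n < 3:
        raise TpsEvolError("neighbor-joining needs >= 3 taxa")
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise TpsEvolError("distances must be finite and nonnegative")
    taxa = dendropy.TaxonNamespace(ids)
    nodes = [
        dendropy.Node(taxon=taxa.get_taxon(label=name)) for name in ids
    ]
    active = list(range(n))
    D = d.copy()

    def join(i, j, li, lj):
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = max(0.0, li)
        nj.edge.length = max(0.0, lj)
        return parent

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        best = (np.inf, None)
        for a in range(m):
            for b in range(a + 1, m):
                if Qm[a, b] < best[0] - 1e-12:
                    best = (Qm[a, b], (a, b))
        a, b = best[1]
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        parent = join(i, j, li, lj)
        # distances from the new node
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    # closed-form star resolution for the last three
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = dendropy.Node()
    for node_idx, length in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[node_idx])
        nodes[node_idx].edge.length = max(0.0, length)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def bootstrap_support(
    pa: ProteinAlignment,
    builder=None,
    n_reps: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """Column-resampling bootstrap support on the point-estimate tree.

    ``builder`` maps a ProteinAlignment to a PhyloTree; the default is
    JTT-distance neighbor-joining.  Support on each internal edge is the
    percentage of replicate trees containing the same bipartition, stored
    as the internal node label.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if builder is None:
        def builder(al):
            return nj_tree(jtt_distance_matrix(al), al.ids)

    point = builder(pa)
    rng = np.random.default_rng(seed)
    ncol = pa.ncol
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep = ProteinAlignment(
            ids=list(pa.ids),
            rows=["".join(r[c] for c in cols) for r in pa.rows],
        )
        for bp in builder(rep).bipartition_sets():
            counts[bp] = counts.get(bp, 0) + 1
    all_leaves = frozenset(point.leaf_ids)
    for node in point.tree.preorder_node_iter():
        if node.is_leaf() or node is point.tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not (1 < len(below) < len(all_leaves) - 1):
            continue
        key = min(below, all_leaves - below, key=sorted)
        node.label = str(
            round(100.0 * counts.get(key, 0) / n_reps)
        )
    return point


# ------------------------------------------------------ duplicates & fates

def find_species_duplicate_pairs(
    t: PhyloTree, species_map: dict[str, str]
) -> tuple[list[DuplicatePair], list[list[str]]]:
    """Same-species cherries = recently duplicated gene pairs.

    Returns (pairs, unresolved): a polytomy whose leaf children share a
    species is reported in ``unresolved`` and no pairs are called inside
    it.
    """
    pairs, unresolved = [], []
    for node in t.tree.preorder_node_iter():
        kids = node.child_nodes()
        leaf_kids = [k for k in kids if k.is_leaf()]
        if len(kids) == 2 and len(leaf_kids) == 2:
            a, b = sorted(k.taxon.label for k in leaf_kids)
            if species_map.get(a) == species_map.get(b) and species_map.get(a):
                pairs.append(
                    DuplicatePair(
                        gene_a=a, gene_b=b, species=species_map[a]
                    )
                )
        elif len(kids) > 2 and len(leaf_kids) >= 2:
            labels = sorted(k.taxon.label for k in leaf_kids)
            by_sp: dict[str, list[str]] = {}
            for lb in labels:
                by_sp.setdefault(species_map.get(lb, "?"), []).append(lb)
            if any(len(v) >= 2 for v in by_sp.values()):
                unresolved.append(labels)
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs, unresolved


def count_ancestral_lineages(
    t: PhyloTree,
    side_map: dict[str, str],
    outgroup: str | None = None,
) -> tuple[int, list[dict]]:
    """Minimum ancestral-gene count at the monocot-dicot split.

    Finds maximal clades whose leaves all lie on one side of the split,
    merges sister clades of opposite sides into single orthologous
    groups, and counts the groups.  Pruning an entire group lowers the
    count by exactly 1 (monotonicity).  ``side_map`` maps species to
    'monocot'/'dicot'; the outgroup leaf (if named) is ignored.
    """
    work = t.copy()
    if outgroup is not None and outgroup in work.leaf_ids:
        work = work.subtree_for_leaves(
            [x for x in work.leaf_ids if x != outgroup]
        )
    sides: dict[int, set] = {}
    for leaf in work.tree.leaf_node_iter():
        label = leaf.taxon.label
        species = label.split("|")[0] if "|" in label else label
        side = side_map.get(label) or side_map.get(species)
        if side is None:
            raise TreeDataMismatchError(f"no monocot/dicot side for {label}")
        sides[id(leaf)] = {side}
    for node in work.tree.postorder_internal_node_iter():
        sides[id(node)] = set().union(
            *(sides[id(c)] for c in node.child_nodes())
        )

    def is_maximal(node):
        if len(sides[id(node)]) != 1:
            return False
        parent = node.parent_node
        return parent is None or len(sides[id(parent)]) > 1

    maximal = [
        n
        for n in work.tree.preorder_node_iter()
        if is_maximal(n)
    ]
    groups = []
    consumed = set()
    for node in maximal:
        if id(node) in consumed:
            continue
        group_nodes = [node]
        parent = node.parent_node
        if parent is not None:
            siblings = [
                s
                for s in parent.child_nodes()
                if s is not node
                and id(s) not in consumed
                and s in maximal
                and sides[id(s)] != sides[id(node)]
            ]
            if siblings:
                group_nodes.append(siblings[0])
                consumed.add(id(siblings[0]))
        consumed.add(id(node))
        leaves = sorted(
            lf.taxon.label
            for gn in group_nodes
            for lf in ([gn] if gn.is_leaf() else gn.leaf_iter())
        )
        groups.append(
            {
                "members": leaves,
                "sides": sorted(
                    set().union(*(sides[id(g)] for g in group_nodes))
                ),
            }
        )
    return len(groups), groups


def classify_duplication_mechanism(
    p: DuplicatePair,
    gene_table: pd.DataFrame,
    block_table: list[dict] | None = None,
    tandem_rule: int = DEFAULT_TANDEM_DISTANCE,
) -> str:
    """Tandem / block-based / unknown call for one duplicate pair.

    Tandem: same chromosome and gene spans within ``tandem_rule`` bp.
    Otherwise, if the two genes fall in the paired regions of a
    paralogous-block entry, the entry's kind ('whole_genome_block' by
    default, or 'segmental') is returned.  Missing coordinates give
    'unknown', never an error.
    """
    gt = gene_table.set_index("gene_id")
    try:
        ga, gb = gt.loc[p.gene_a], gt.loc[p.gene_b]
    except KeyError:
        return "unknown"

    def coords(row):
        if pd.isna(row.get("chromosome")) or pd.isna(row.get("start")):
            return None
        return str(row["chromosome"]), int(row["start"]), int(row["end"])

    ca, cb = coords(ga), coords(gb)
    if ca and cb and ca[0] == cb[0]:
        gap = max(ca[1], cb[1]) - min(ca[2], cb[2])
        if gap <= tandem_rule:
            return "tandem"
    if block_table and ca and cb:
        for entry in block_table:
            kind = entry.get("kind", "whole_genome_block")
            ra, rb = entry["regionA"], entry["regionB"]
            if (_in_region(ca, ra) and _in_region(cb, rb)) or (
                _in_region(ca, rb) and _in_region(cb, ra)
            ):
                return kind
    return "unknown"


def _in_region(coords, region) -> bool:
    chrom, start, end = coords
    rchrom, rstart, rend = region
    return str(chrom) == str(rchrom) and start >= rstart and end <= rend


def classify_duplicate_fate(p: DuplicatePair, em: ExpressionMatrix) -> str:
    """Expression-based duplicate-fate call.

    Over the conditions assayed for both genes (missing calls dropped):
    both expressed everywhere -> shared_expression; exactly one silent
    everywhere -> nonfunctionalization_candidate; one broad (all assayed)
    and the other a strict nonempty subset -> subfunctionalization
    candidate; anything else -> divergent.  A gene absent from the matrix
    gives 'unknown'.
    """
    if p.gene_a not in em.calls or p.gene_b not in em.calls:
        return "unknown"
    conds = [
        c
        for c in em.conditions
        if em.call(p.gene_a, c) != "missing"
        and em.call(p.gene_b, c) != "missing"
    ]
    if not conds:
        return "unknown"
    ea = {c for c in conds if em.call(p.gene_a, c) == "expressed"}
    eb = {c for c in conds if em.call(p.gene_b, c) == "expressed"}
    full = set(conds)
    if ea == full and eb == full:
        return "shared_expression"
    if (not ea) != (not eb):  # exactly one silent
        return "nonfunctionalization_candidate"
    if not ea and not eb:
        return "divergent"
    for broad, other in ((ea, eb), (eb, ea)):
        if broad == full and other and other < full:
            return "subfunctionalization_candidate"
    return "divergent"


def duplicate_pair_table(
    pairs: list[DuplicatePair],
    gene_table: pd.DataFrame | None = None,
    block_table: list[dict] | None = None,
    em: ExpressionMatrix | None = None,
    tandem_rule: int = DEFAULT_TANDEM_DISTANCE,
) -> pd.DataFrame:
    """Mechanism and fate calls for every pair, TSV-ready."""
    rows = []
    for p in pairs:
        if gene_table is not None:
            p.mechanism = classify_duplication_mechanism(
                p, gene_table, block_table, tandem_rule
            )
        if em is not None:
            p.fate = classify_duplicate_fate(p, em)
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "species": p.species,
                "mechanism": p.mechanism,
                "fate": p.fate,
            }
        )
    return pd.DataFrame(rows)
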
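"""Counting-based pairwise dN/dS estimation (NG86 and a YN00-style method).

NG86 counts synonymous/nonsynonymous sites and differences with equal
weights and corrects the proportions with the one-parameter (Jukes-Cantor
form) formula.  The YN00-style estimator keeps the same counting skeleton
but weights both the site fractions and the multi-hit mutational pathways
by target-codon frequency and the transition/transversion ratio kappa,
estimated from fourfold-degenerate sites.  Because pathway weights exclude
omega and the distance correction keeps the one-parameter form, the
estimator collapses exactly onto NG86 when codon frequencies are equal and
kappa = 1 — the property the test suite checks.

Domain-partitioned scatter (TPS vs TPP columns per pair) and the paired
t-test on (omega_TPP - omega_TPS) reproduce the domain-relaxation
comparison for the TPS family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._codons import (
    AA_BY_INDEX,
    CODON_INDEX,
    N_SENSE,
    SENSE_CODONS,
    STOP_CODONS,
    STEP_DST,
    STEP_IS_NONSYN,
    STEP_IS_TS,
    STEP_POS,
    STEP_SRC,
    is_transition,
)
from .core import CodonAlignment, DomainPartition, mask_gapped_columns
from .errors import TpsEvolError

UNDEFINED_DS0 = "undefined_dS0"
SATURATED = "saturated"

# dS beyond this is treated as saturated for scatter/report purposes
DS_SATURATION_GUARD = 3.0


@dataclass
class PairwiseRateEstimate:
    pair: tuple[str, str]
    method: str
    S: float
    N: float
    Sd: float
    Nd: float
    dS: float | None
    dN: float | None
    omega: float | None
    kappa: float | None = None
    n_codons: int = 0
    flags: list[str] = field(default_factory=list)


# ------------------------------------------------------------- site counts

def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous site counts of one sense codon.

    Each codon position contributes one site, split as (synonymous
    one-step neighbours) / (viable one-step neighbours); changes into stop
    codons are excluded from the viable set, so s + n == 3 exactly.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise TpsEvolError(f"stop codon {codon} has no site decomposition")
    if codon not in CODON_INDEX:
        raise TpsEvolError(f"not a sense codon: {codon!r}")
    aa = AA_BY_INDEX[CODON_INDEX[codon]]
    s = 0.0
    for p in range(3):
        syn = viable = 0
        for nt in "ACGT":
            if nt == codon[p]:
                continue
            alt = codon[:p] + nt + codon[p + 1 :]
            if alt in STOP_CODONS:
                continue
            viable += 1
            if AA_BY_INDEX[CODON_INDEX[alt]] == aa:
                syn += 1
        if viable:
            s += syn / viable
    return s, 3.0 - s


def _weighted_sites_all(pi: np.ndarray, kappa: float) -> np.ndarray:
    """Synonymous-site count per sense codon under (pi, kappa) weighting.

    Vectorized over the precomputed single-step tables; reduces to
    ``ng86_sites`` when pi is uniform and kappa == 1.
    """
    w = pi[STEP_DST] * np.where(STEP_IS_TS, kappa, 1.0)
    denom = np.zeros((N_SENSE, 3))
    syn = np.zeros((N_SENSE, 3))
    np.add.at(denom, (STEP_SRC, STEP_POS), w)
    np.add.at(syn, (STEP_SRC, STEP_POS), w * (~STEP_IS_NONSYN))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, syn / denom, 0.0)
    return frac.sum(axis=1)


# ------------------------------------------------------------- pathways

def _enumerate_paths(i: int, j: int):
    """Minimal mutational pathways between two sense codons.

    Each path is (targets, ts_flags, syn_flags) per step.  Paths through
    stop codons are dropped; if every minimal path hits a stop (does not
    occur in the standard code for <=2 differences, rare at 3), all paths
    are retained instead.
    """
    a, b = SENSE_CODONS[i], SENSE_CODONS[j]
    diffs = [p for p in range(3) if a[p] != b[p]]
    paths = []
    for order in itertools.permutations(diffs):
        cur = a
        targets, ts_flags, syn_flags, ok = [], [], [], True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            targets.append(CODON_INDEX[nxt])
            ts_flags.append(is_transition(cur[p], b[p]))
            syn_flags.append(
                AA_BY_INDEX[CODON_INDEX[cur]] == AA_BY_INDEX[CODON_INDEX[nxt]]
            )
            cur = nxt
        if ok:
            paths.append((tuple(targets), tuple(ts_flags), tuple(syn_flags)))
    if not paths:
        # never hit for the standard code (checked in the test suite)
        raise TpsEvolError(
            f"no stop-free minimal path between {a} and {b}"
        )
    return paths


_PATH_CACHE: dict[tuple[int, int], list] = {}


def _paths(i: int, j: int):
    key = (i, j)
    if key not in _PATH_CACHE:
        _PATH_CACHE[key] = _enumerate_paths(i, j)
    return _PATH_CACHE[key]


def _count_differences(
    idx1: np.ndarray,
    idx2: np.ndarray,
    pi: np.ndarray | None,
    kappa: float,
) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over pathways.

    With ``pi is None`` all minimal pathways weigh equally (NG86).  With
    frequencies, a path's weight is kappa^(transitions) times the
    symmetrized product of target-codon frequencies over the two reading
    directions, which keeps the estimate invariant to swapping sequences.
    """
    sd = nd = 0.0
    for i, j in zip(idx1, idx2):
        if i == j:
            continue
        fw = _paths(int(i), int(j))
        if pi is None:
            weights = np.ones(len(fw))
        else:
            # forward weight = prod(pi over intermediates) * pi[j]; reverse
            # reading gives prod(intermediates) * pi[i]; their sum makes the
            # estimate symmetric in the two sequences
            weights = np.empty(len(fw))
            for k, (tg, ts, syn) in enumerate(fw):
                inter = np.prod(pi[list(tg[:-1])]) if len(tg) > 1 else 1.0
                weights[k] = (
                    kappa ** sum(ts) * inter * (pi[int(i)] + pi[int(j)])
                )
        weights = weights / weights.sum()
        for w, (tg, ts, syn) in zip(weights, fw):
            n_syn = sum(syn)
            sd += w * n_syn
            nd += w * (len(syn) - n_syn)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    """One-parameter multiple-hit correction; None when saturated."""
    if p >= 0.75:
        return None
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def _codon_indices(seq: list[str] | str, label: str) -> np.ndarray:
    if isinstance(seq, str):
        seq = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    try:
        return np.asarray([CODON_INDEX[c.upper()] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise TpsEvolError(
            f"{label}: non-sense codon {exc.args[0]!r} in gap-free input"
        ) from None


def ng86_pair(
    seq1, seq2, ids: tuple[str, str] = ("seq1", "seq2")
) -> PairwiseRateEstimate:
    """Nei-Gojobori (1986) pairwise estimate on gap-free codon sequences."""
    i1 = _codon_indices(seq1, ids[0])
    i2 = _codon_indices(seq2, ids[1])
    if i1.size != i2.size:
        raise TpsEvolError("sequences differ in codon count")
    if i1.size == 0:
        raise TpsEvolError("empty sequences")
    s_per = np.asarray([ng86_sites(c)[0] for c in SENSE_CODONS])
    S = float(s_per[i1].sum() + s_per[i2].sum()) / 2.0
    N = 3.0 * i1.size - S
    Sd, Nd = _count_differences(i1, i2, pi=None, kappa=1.0)
    return _finish_estimate(
        ids, "NG86", S, N, Sd, Nd, kappa=None, n_codons=int(i1.size)
    )


def _finish_estimate(ids, method, S, N, Sd, Nd, kappa, n_codons, flags=None):
    flags = list(flags or [])
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    omega = None
    if dS is None or dN is None:
        flags.append(SATURATED)
    elif dS == 0.0:
        flags.append(UNDEFINED_DS0)
    else:
        omega = dN / dS
    return PairwiseRateEstimate(
        pair=tuple(ids),
        method=method,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        dS=dS,
        dN=dN,
        omega=omega,
        kappa=kappa,
        n_codons=n_codons,
        flags=flags,
    )


def f3x4_frequencies(codon_index_arrays: list[np.ndarray]) -> np.ndarray:
    """F3x4 codon frequencies from observed codons (61-vector, floored)."""
    counts = np.zeros((3, 4))
    nt_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for arr in codon_index_arrays:
        for i in arr:
            codon = SENSE_CODONS[int(i)]
            for p in range(3):
                counts[p, nt_idx[codon[p]]] += 1
    counts += 1e-12
    pos = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos[0, nt_idx[c[0]]] * pos[1, nt_idx[c[1]]] * pos[2, nt_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    pi = np.maximum(pi, 1e-6)
    return pi / pi.sum()


def _is_fourfold(codon: str) -> bool:
    aa = AA_BY_INDEX[CODON_INDEX[codon]]
    for nt in "ACGT":
        alt = codon[:2] + nt
        if alt in STOP_CODONS or AA_BY_INDEX[CODON_INDEX[alt]] != aa:
            return False
    return True


_FOURFOLD = np.asarray([_is_fourfold(c) for c in SENSE_CODONS])


def estimate_kappa_fourfold(
    idx1: np.ndarray, idx2: np.ndarray, default: float = 2.0
) -> tuple[float, bool]:
    """kappa from the K80 fit at sites fourfold-degenerate in both codons.

    Returns (kappa, estimated_flag); falls back to ``default`` when too
    few usable sites or the K80 logs are undefined.
    """
    mask = _FOURFOLD[idx1] & _FOURFOLD[idx2]
    n = int(mask.sum())
    if n < 10:
        return default, False
    ts = tv = 0
    for i, j in zip(idx1[mask], idx2[mask]):
        a, b = SENSE_CODONS[int(i)][2], SENSE_CODONS[int(j)][2]
        if a == b:
            continue
        if is_transition(a, b):
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        return default, False
    A = -0.5 * np.log(a1) + 0.25 * np.log(a2)
    B = -0.5 * np.log(a2)
    if B <= 1e-9:
        return 30.0, True
    return float(np.clip(2.0 * A / B, 0.1, 30.0)), True


def yn00_pair(
    seq1,
    seq2,
    freqs="f3x4",
    kappa: float | None = None,
    ids: tuple[str, str] = ("seq1", "seq2"),
    max_iter: int = 50,
    tol: float = 1e-8,
) -> PairwiseRateEstimate:
    """Frequency- and kappa-weighted pairwise dN/dS estimate.

    ``freqs`` may be 'f3x4' (computed from the pair, default), 'equal', or
    a 61-vector.  ``kappa=None`` estimates kappa from fourfold-degenerate
    sites; passing a number fixes it.  The kappa/omega update loop runs to
    convergence (the fixed point is reached after the first pass because
    pathway weights deliberately exclude omega; see the methods note).
    """
    i1 = _codon_indices(seq1, ids[0])
    i2 = _codon_indices(seq2, ids[1])
    if i1.size != i2.size:
        raise TpsEvolError("sequences differ in codon count")
    if isinstance(freqs, str):
        if freqs == "equal":
            pi = np.full(N_SENSE, 1.0 / N_SENSE)
        elif freqs == "f3x4":
            pi = f3x4_frequencies([i1, i2])
        else:
            raise ValueError(f"unknown frequency model {freqs!r}")
    else:
        pi = np.asarray(freqs, dtype=float)
        pi = pi / pi.sum()

    flags = []
    if kappa is None:
        kap, ok = estimate_kappa_fourfold(i1, i2)
        if not ok:
            flags.append("kappa_fallback")
    else:
        kap = float(kappa)

    prev = (np.inf, np.inf)
    est = None
    for it in range(max_iter):
        s_per = _weighted_sites_all(pi, kap)
        S = float(s_per[i1].sum() + s_per[i2].sum()) / 2.0
        N = 3.0 * i1.size - S
        Sd, Nd = _count_differences(i1, i2, pi=pi, kappa=kap)
        est = _finish_estimate(
            ids, "YN00", S, N, Sd, Nd, kappa=kap,
            n_codons=int(i1.size), flags=flags,
        )
        cur = (est.dS if est.dS is not None else np.inf,
               est.dN if est.dN is not None else np.inf)
        if abs(cur[0] - prev[0]) < tol and abs(cur[1] - prev[1]) < tol:
            break
        prev = cur
    else:
        est.flags.append("nonconverged")
    return est


# ------------------------------------------------------- domain scatter

@dataclass
class DomainRateTable:
    """One (omega_TPS, omega_TPP) point per unordered sequence pair."""

    table: pd.DataFrame  # columns: id1, id2, omega_TPS, omega_TPP, flags

    def defined_pairs(self) -> pd.DataFrame:
        t = self.table
        return t[t["omega_TPS"].notna() & t["omega_TPP"].notna()]


def _pair_domain_estimate(ca, cols, i, j, method, domain):
    row_i = [ca.rows[i][c] for c in cols]
    row_j = [ca.rows[j][c] for c in cols]
    if not cols:
        return None, [f"{domain}_no_columns"]
    fn = yn00_pair if method == "YN00" else ng86_pair
    est = fn(row_i, row_j, ids=(ca.ids[i], ca.ids[j]))
    if est.omega is None:
        return None, [f"{domain}_{est.flags[-1]}" if est.flags else domain]
    if est.dS is not None and est.dS > DS_SATURATION_GUARD:
        return None, [f"{domain}_{SATURATED}"]
    return est.omega, []


def domain_rate_scatter(
    ca: CodonAlignment,
    part: DomainPartition,
    method: str = "YN00",
) -> DomainRateTable:
    """Per-pair omega in the TPS and TPP column blocks (pairwise deletion).

    Pairs where a domain yields no comparable columns, dS = 0, or a
    saturated distance are flagged rather than silently dropped.
    """
    part.validate_for(ca)
    pair_cols = mask_gapped_columns(ca, "pairwise_deletion")
    rows = []
    n = len(ca.ids)
    for a in range(n):
        for b in range(a + 1, n):
            usable = set(pair_cols[(ca.ids[a], ca.ids[b])])
            flags: list[str] = []
            values = {}
            for dom in ("TPS", "TPP"):
                cols = sorted(usable & part.domains.get(dom, frozenset()))
                val, fl = _pair_domain_estimate(ca, cols, a, b, method, dom)
                values[dom] = val
                flags += fl
            rows.append(
                {
                    "id1": ca.ids[a],
                    "id2": ca.ids[b],
                    "omega_TPS": values["TPS"],
                    "omega_TPP": values["TPP"],
                    "flags": ";".join(flags),
                }
            )
    return DomainRateTable(table=pd.DataFrame(rows))


def paired_domain_test(t: DomainRateTable):
    """Paired two-sided t-test on (omega_TPP - omega_TPS).

    Only pairs with both domain estimates defined enter; an all-zero
    difference vector returns t=0, p=1.
    """
    from .conservation import GroupComparisonResult

    d = t.defined_pairs()
    if len(d) < 2:
        raise TpsEvolError("need >= 2 pairs with both domain estimates")
    diffs = d["omega_TPP"].to_numpy(float) - d["omega_TPS"].to_numpy(float)
    if np.allclose(diffs, 0.0):
        return GroupComparisonResult(
            ("TPP", "TPS"), (len(d), len(d)), 0.0,
            float(len(d) - 1), 1.0, "paired",
        )
    res = stats.ttest_rel(
        d["omega_TPP"].to_numpy(float), d["omega_TPS"].to_numpy(float)
    )
    return GroupComparisonResult(
        group_labels=("TPP", "TPS"),
        n=(len(d), len(d)),
        statistic=float(res.statistic),
        df=float(len(d) - 1),
        p_value=float(res.pvalue),
        test_variant="paired",
    )


def rate_table_tsv(estimates: list[PairwiseRateEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "id1": e.pair[0],
                "id2": e.pair[1],
                "method": e.method,
                "S": e.S,
                "N": e.N,
                "Sd": e.Sd,
                "Nd": e.Nd,
                "dS": e.dS,
                "dN": e.dN,
                "omega": e.omega,
                "kappa": e.kappa,
                "flags": ";".join(e.flags),
            }
        )
    return pd.DataFrame(rows)
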
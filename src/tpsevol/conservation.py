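"""Pairwise identity, class-wise identity statistics, catalytic residues.

Class I and class II TPS proteins are far more similar within than between
classes; the package reproduces the pairwise-identity distributions and the
independent-sample t-test on within- versus between-class identities, and
maps catalytic residues of a reference enzyme (e.g. the E. coli OtsA
outgroup) through the alignment to count absolutely conserved positions
per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ProteinAlignment
from .errors import MissingClassError, UndefinedIdentityError


@dataclass
class IdentityMatrix:
    ids: list[str]
    matrix: np.ndarray  # percent identities, symmetric, diagonal 100
    gap_policy: str

    def value(self, i: str, j: str) -> float:
        return float(self.matrix[self.ids.index(i), self.ids.index(j)])


@dataclass
class GroupComparisonResult:
    group_labels: tuple[str, str]
    n: tuple[int, int]
    statistic: float
    df: float
    p_value: float
    test_variant: str
    summaries: dict | None = None


def pairwise_identity(
    pa: ProteinAlignment,
    i: str,
    j: str,
    denominator: str = "both_ungapped",
) -> float:
    """Percent identity between two gapped rows.

    ``denominator`` chooses what counts as a comparable position:
    'both_ungapped' (default) uses columns where neither row has a gap;
    'alignment_length' uses every column; 'shorter_seq' divides by the
    shorter ungapped sequence length.
    """
    a, b = pa.row(i), pa.row(j)
    matches = comparable = 0
    for x, y in zip(a, b):
        both = x != "-" and y != "-"
        if both:
            comparable += 1
            if x == y:
                matches += 1
    if denominator == "both_ungapped":
        denom = comparable
    elif denominator == "alignment_length":
        denom = len(a)
    elif denominator == "shorter_seq":
        denom = min(
            sum(1 for x in a if x != "-"), sum(1 for y in b if y != "-")
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise UndefinedIdentityError(
            f"no comparable positions between {i} and {j}"
        )
    return 100.0 * matches / denom


def identity_matrix(
    pa: ProteinAlignment, denominator: str = "both_ungapped"
) -> IdentityMatrix:
    n = len(pa.ids)
    if n < 2:
        raise UndefinedIdentityError("need at least 2 sequences")
    m = np.full((n, n), 100.0)
    for a in range(n):
        for b in range(a + 1, n):
            v = pairwise_identity(pa, pa.ids[a], pa.ids[b], denominator)
            m[a, b] = m[b, a] = v
    return IdentityMatrix(ids=list(pa.ids), matrix=m, gap_policy=denominator)


def _five_number(v: np.ndarray) -> dict:
    return {
        "n": int(v.size),
        "min": float(np.min(v)),
        "q1": float(np.percentile(v, 25)),
        "median": float(np.median(v)),
        "q3": float(np.percentile(v, 75)),
        "max": float(np.max(v)),
    }


def group_identity_stats(
    m: IdentityMatrix, class_map: dict[str, str]
) -> dict:
    """Split pairwise identities into I-I, II-II and I-II distributions.

    Every unordered pair lands in exactly one distribution, so the sizes
    sum to n(n-1)/2.  Returns the raw vectors plus boxplot-style
    five-number summaries.
    """
    for name in m.ids:
        if name not in class_map:
            raise MissingClassError(f"no class label for {name}")
    dists: dict[str, list[float]] = {"I-I": [], "II-II": [], "I-II": []}
    n = len(m.ids)
    for a in range(n):
        for b in range(a + 1, n):
            ca, cb = class_map[m.ids[a]], class_map[m.ids[b]]
            key = f"{ca}-{cb}" if ca == cb else "I-II"
            dists[key].append(float(m.matrix[a, b]))
    out = {k: np.asarray(v) for k, v in dists.items()}
    return {
        "distributions": out,
        "summaries": {
            k: (_five_number(v) if v.size else {"n": 0})
            for k, v in out.items()
        },
    }


def independent_t_test(
    a, b, variant: str = "welch"
) -> GroupComparisonResult:
    """Two-sided independent-sample t-test (Welch default, pooled optional).

    Degenerate inputs with zero variance in both groups and equal means
    return t=0, p=1 rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in each group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in t-test input")
    equal_var = variant == "pooled"
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        df = a.size + b.size - 2 if equal_var else float(a.size + b.size - 2)
        return GroupComparisonResult(
            ("a", "b"), (a.size, b.size), 0.0, float(df), 1.0, variant
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
        df = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
    return GroupComparisonResult(
        group_labels=("a", "b"),
        n=(a.size, b.size),
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        test_variant=variant,
    )


def label_permutation_test(a, b, n_perm: int = 999, seed: int = 0) -> float:
    """Optional permutation p-value for the group-mean difference.

    Provided as a caveat check: pairwise identities are not independent
    observations, so the t-test p-value is approximate.  Off by default in
    all reports.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        diff = abs(pooled[: a.size].mean() - pooled[a.size :].mean())
        if diff >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def map_reference_positions(
    pa: ProteinAlignment, ref_id: str, ref_positions: list[int]
) -> list[int]:
    """Map 1-based ungapped residue indices of ``ref_id`` to columns."""
    row = pa.row(ref_id)
    cols = [c for c, aa in enumerate(row) if aa != "-"]
    out = []
    for p in ref_positions:
        if not (1 <= p <= len(cols)):
            raise IndexError(
                f"reference position {p} outside 1..{len(cols)}"
            )
        out.append(cols[p - 1])
    return out


def catalytic_site_conservation(
    pa: ProteinAlignment,
    ref_id: str,
    ref_positions: list[int],
    class_map: dict[str, str],
) -> dict:
    """Absolute conservation of reference residues within each class.

    A reference position counts as conserved in a class iff *every* member
    of that class carries the reference residue at the mapped column.
    Returns per-class conserved counts and a per-position table.
    """
    cols = map_reference_positions(pa, ref_id, ref_positions)
    ref_row = pa.row(ref_id)
    classes = sorted({v for k, v in class_map.items() if k != ref_id})
    members = {
        cl: [g for g in pa.ids if g != ref_id and class_map.get(g) == cl]
        for cl in classes
    }
    table = []
    counts = {cl: 0 for cl in classes}
    for p, c in zip(ref_positions, cols):
        ref_aa = ref_row[c]
        for cl in classes:
            conserved = all(pa.row(g)[c] == ref_aa for g in members[cl])
            counts[cl] += conserved
            table.append(
                {
                    "ref_position": p,
                    "ref_residue": ref_aa,
                    "class": cl,
                    "conserved": "yes" if conserved else "no",
                }
            )
    return {"counts": counts, "table": pd.DataFrame(table)}
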
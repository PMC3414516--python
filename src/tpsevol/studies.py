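"""Self-contained calibration studies on synthetic data with known truth.

These functions define the package's standard verification experiments:
exactness of the pruning likelihood against brute-force state summation,
null calibration of the branch-model LRT, parameter recovery for the
two-ratio contrast between strongly and weakly constrained clades,
agreement of the YN00-style estimator with its NG86 limit, power of the
paired domain-relaxation test, and the closed loops for gene-structure
and duplicate-fate classification.  Both the test suite and the
reproduction script drive the package exclusively through these entry
points, so every reported number is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from ._codons import CODON_INDEX, N_SENSE, SENSE_CODONS
from .branch_models import (
    CodonFrequencies,
    SpectralQ,
    fit_branch_model,
    gy94_rate_matrix,
    likelihood_ratio_test,
    pruning_loglik,
)
from .core import CodonAlignment, GeneRecord
from .family import DuplicatePair, classify_duplicate_fate
from .gene_structure import classify_by_structure, count_introns
from .io import read_gff3_gene_models
from .pairwise_rates import (
    domain_rate_scatter,
    ng86_pair,
    paired_domain_test,
    yn00_pair,
)
from .simulate import (
    DomainBlock,
    SimulationSpec,
    balanced_tree,
    simulate_codon_alignment,
    simulate_expression_matrix,
    simulate_gene_models,
)
from .trees import PhyloTree

_NT = "ACGT"


def plantlike_codon_freqs() -> CodonFrequencies:
    """Uneven F3x4-style frequencies with mild GC/position structure,
    used as the generating distribution in the calibration studies."""
    pos = np.array(
        [
            [0.28, 0.21, 0.30, 0.21],
            [0.29, 0.22, 0.19, 0.30],
            [0.22, 0.27, 0.26, 0.25],
        ]
    )
    idx = {n: k for k, n in enumerate(_NT)}
    pi = np.array(
        [
            pos[0, idx[c[0]]] * pos[1, idx[c[1]]] * pos[2, idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return CodonFrequencies(model="F3x4", pi=pi / pi.sum())


# ---------------------------------------------- pruning exactness

def pruning_exactness_error(seed: int = 0, n_trees: int = 3) -> float:
    """Max |pruning - exhaustive| over random 4-taxon, 3-column datasets.

    The brute force sums the joint likelihood over all 61^2 internal-node
    codon assignments of the derooted quartet, per column.
    """
    rng = np.random.default_rng(seed)
    freqs = plantlike_codon_freqs()
    worst = 0.0
    for _ in range(n_trees):
        bl = rng.uniform(0.05, 0.4, size=5)
        nwk = (
            f"((a:{bl[0]:.17g},b:{bl[1]:.17g}):{bl[4]:.17g},"
            f"c:{bl[2]:.17g},d:{bl[3]:.17g});"
        )
        tree = PhyloTree.from_newick(nwk)
        ca = CodonAlignment(
            ids=list("abcd"),
            rows=[
                [SENSE_CODONS[i] for i in rng.integers(0, N_SENSE, 3)]
                for _ in range(4)
            ],
        )
        kappa, omega = rng.uniform(1, 4), rng.uniform(0.05, 1.0)
        lnl = pruning_loglik(tree, ca, kappa, omega, freqs)
        sq = SpectralQ(gy94_rate_matrix(kappa, omega, freqs))
        Pa, Pb = sq.P(bl[0]), sq.P(bl[1])
        Pc, Pd, Px = sq.P(bl[2]), sq.P(bl[3]), sq.P(bl[4])
        total = 0.0
        for col in range(3):
            s = {x: CODON_INDEX[ca.row(x)[col]] for x in "abcd"}
            site = 0.0
            for r in range(N_SENSE):
                inner = 0.0
                for x in range(N_SENSE):
                    inner += Px[r, x] * Pa[x, s["a"]] * Pb[x, s["b"]]
                site += (
                    float(freqs.pi[r]) * inner * Pc[r, s["c"]] * Pd[r, s["d"]]
                )
            total += np.log(site)
        worst = max(worst, abs(lnl - total))
    return worst


# ---------------------------------------------- LRT null calibration

def _warm_two_ratio(tree, ca, foreground, fit0, seed):
    return fit_branch_model(
        tree,
        ca,
        model="two_ratio",
        foreground=foreground,
        n_starts=1,
        seed=seed,
        init={
            "kappa": fit0.kappa,
            "omegas": [fit0.omega_by_class["all"]] * 2,
            "t": {frozenset(k): v for k, v in fit0.branch_lengths.items()},
        },
    )


def lrt_null_rejection_rate(
    n_reps: int = 200,
    seed: int = 0,
    n_taxa: int = 8,
    n_codons: int = 300,
    omega: float = 0.1,
    kappa: float = 2.0,
) -> dict:
    """Two-ratio vs one-ratio rejection rate on one-ratio simulations.

    Data are simulated under a single omega on the standard balanced tree
    with uneven codon frequencies; each replicate is fitted under both
    models (the alternative warm-started from the null) and 2dl compared
    to the chi-square(1) 5% cutoff (3.841).
    """
    rng = np.random.default_rng(seed)
    tree = balanced_tree(n_taxa, depth=0.5)
    fg = frozenset(f"t{i + 1}" for i in range(n_taxa // 2))
    freqs = plantlike_codon_freqs()
    stats = np.empty(n_reps)
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        ca, _ = simulate_codon_alignment(
            SimulationSpec(
                tree=tree,
                kappa=kappa,
                omega_by_class={"background": omega},
                n_codons=n_codons,
                seed=rep_seed,
                freqs=freqs,
            )
        )
        fit0 = fit_branch_model(
            tree, ca, model="one_ratio", n_starts=1, seed=rep_seed
        )
        fit1 = _warm_two_ratio(tree, ca, fg, fit0, rep_seed)
        stats[rep] = likelihood_ratio_test(fit0, fit1).statistic
    return {
        "rejection_rate": float(np.mean(stats > 3.841)),
        "mean_statistic": float(stats.mean()),
        "n_reps": n_reps,
    }


# ---------------------------------------------- two-ratio recovery

def two_ratio_recovery(
    n_reps: int = 20,
    seed: int = 0,
    omega_bg: float = 0.065,
    omega_fg: float = 0.35,
    n_taxa: int = 8,
    n_codons: int = 500,
    kappa: float = 2.0,
) -> dict:
    """Recovery of the strong/relaxed clade contrast by the two-ratio fit.

    Mirrors the clade contrast between a strongly purifying background
    (omega 0.065) and a relaxed foreground clade (omega 0.35).  Reports
    the median fitted omegas and the fraction of replicates ordering the
    two correctly.
    """
    rng = np.random.default_rng(seed)
    tree = balanced_tree(n_taxa, depth=0.5)
    fg = frozenset(f"t{i + 1}" for i in range(n_taxa // 2))
    freqs = plantlike_codon_freqs()
    bg_hat, fg_hat = [], []
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        ca, _ = simulate_codon_alignment(
            SimulationSpec(
                tree=tree,
                kappa=kappa,
                omega_by_class={
                    "background": omega_bg,
                    "foreground": omega_fg,
                },
                n_codons=n_codons,
                seed=rep_seed,
                freqs=freqs,
                foreground=fg,
            )
        )
        fit = fit_branch_model(
            tree,
            ca,
            model="two_ratio",
            foreground=fg,
            n_starts=1,
            seed=rep_seed,
        )
        bg_hat.append(fit.omega_by_class["background"])
        fg_hat.append(fit.omega_by_class["foreground"])
    bg_hat, fg_hat = np.asarray(bg_hat), np.asarray(fg_hat)
    return {
        "median_omega_background": float(np.median(bg_hat)),
        "median_omega_foreground": float(np.median(fg_hat)),
        "ordering_fraction": float(np.mean(fg_hat > bg_hat)),
        "true_background": omega_bg,
        "true_foreground": omega_fg,
        "n_reps": n_reps,
    }


# ---------------------------------------------- YN00 limit agreement

def yn00_ng86_limit_deviation(seed: int = 0, n_pairs: int = 6) -> float:
    """Max |YN00(equal, kappa=1) - NG86| over dN and dS on simulated pairs."""
    tree = balanced_tree(8, depth=0.5)
    ca, _ = simulate_codon_alignment(
        SimulationSpec(
            tree=tree,
            kappa=3.0,
            omega_by_class={"background": 0.25},
            n_codons=400,
            seed=seed,
        )
    )
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        i, j = rng.choice(len(ca.ids), size=2, replace=False)
        a = ng86_pair(ca.rows[i], ca.rows[j])
        b = yn00_pair(ca.rows[i], ca.rows[j], freqs="equal", kappa=1.0)
        worst = max(worst, abs(a.dN - b.dN), abs(a.dS - b.dS))
    return worst


# ---------------------------------------------- domain relaxation power

def domain_relaxation_detection(
    n_reps: int = 50,
    seed: int = 0,
    omega_tps: float = 0.08,
    omega_tpp: float = 0.14,
    n_taxa: int = 20,
    n_tps: int = 500,
    n_tpp: int = 300,
    alpha: float = 0.01,
) -> dict:
    """Power of the paired t-test on (omega_TPP - omega_TPS).

    Each replicate simulates a family whose N-terminal block evolves
    under stronger constraint than its C-terminal block, computes the
    per-pair YN00 omegas per domain, and applies the paired test.
    Reports the fraction of replicates with p below ``alpha`` and in the
    relaxed direction.
    """
    rng = np.random.default_rng(seed)
    tree = balanced_tree(n_taxa, depth=0.4)
    hits = 0
    pvals = []
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        ca, truth = simulate_codon_alignment(
            SimulationSpec(
                tree=tree,
                kappa=2.0,
                omega_by_class={"background": omega_tps},
                n_codons=n_tps + n_tpp,
                seed=rep_seed,
                domain_blocks=[
                    DomainBlock("TPS", n_tps, {"background": omega_tps}),
                    DomainBlock("TPP", n_tpp, {"background": omega_tpp}),
                ],
            )
        )
        table = domain_rate_scatter(ca, truth["partition"], method="YN00")
        res = paired_domain_test(table)
        pvals.append(res.p_value)
        if res.p_value < alpha and res.statistic > 0:
            hits += 1
    return {
        "detection_rate": hits / n_reps,
        "median_p": float(np.median(pvals)),
        "n_reps": n_reps,
    }


# ---------------------------------------------- closed-loop classifiers

def structure_classification_accuracy(
    seed: int = 0, n_per_class: int = 10, tmpdir=None
) -> float:
    """Fraction of synthetic gene models whose 16/2-intron structure
    classifies back to the generating class (must be 1.0)."""
    import os
    import tempfile

    _, gff3, truth = simulate_gene_models(
        {"I": n_per_class, "II": n_per_class}, seed=seed
    )
    ctx = tempfile.TemporaryDirectory() if tmpdir is None else None
    base = tmpdir if tmpdir is not None else ctx.name
    path = os.path.join(str(base), "models.gff3")
    with open(path, "w") as fh:
        fh.write(gff3)
    models = read_gff3_gene_models(path)
    if ctx is not None:
        ctx.cleanup()
    hits = 0
    for gid, m in models.items():
        rec = GeneRecord(
            gene_id=gid,
            species="synthetic",
            cds=truth[gid]["cds"],
            exons=m["exons"],
            cds_exons=m["cds_exons"],
            strand=m["strand"],
        )
        label = classify_by_structure(count_introns(rec))
        hits += label == truth[gid]["class"]
    return hits / (2 * n_per_class)


def fate_recovery_accuracy(seed: int = 0, n_pairs: int = 40) -> float:
    """Noise-free expression fixtures must recover every prescribed fate."""
    fates = [
        "shared_expression",
        "nonfunctionalization_candidate",
        "subfunctionalization_candidate",
        "divergent",
    ]
    pairs = [
        (f"a{i}", f"b{i}", fates[i % len(fates)]) for i in range(n_pairs)
    ]
    em = simulate_expression_matrix(
        pairs, [f"cond{i}" for i in range(6)], noise=0.0, seed=seed
    )
    hits = sum(
        classify_duplicate_fate(DuplicatePair(a, b, "synthetic"), em) == f
        for a, b, f in pairs
    )
    return hits / n_pairs
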
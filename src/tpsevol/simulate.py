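"""Synthetic-data generators with known truth for every pipeline stage.

Codon alignments are evolved along a fixed tree under the same GY94
process the fitting code assumes (branch-class-specific omega, optional
TPS/TPP column blocks with their own omega), gene models realize
prescribed intron counts (16 for class I, 2 for class II), and expression
matrices realize prescribed duplicate-pair fates with optional call
noise.  Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codons import SENSE_CODONS
from .branch_models import CodonFrequencies, SpectralQ, gy94_rate_matrix
from .core import CodonAlignment, DomainPartition, ExpressionMatrix
from .errors import TpsEvolError
from .trees import PhyloTree

DEFAULT_INTRON_RULE = {"I": 16, "II": 2}


def balanced_tree(
    n_leaves: int, depth: float = 0.5, prefix: str = "t"
) -> PhyloTree:
    """Balanced(ish) bifurcating tree with uniform root-to-tip depth.

    The default 8-leaf, total-depth-1.0 (root-to-tip 0.5) configuration is
    the package's standard small test tree: fast and identifiable.
    """
    labels = [f"{prefix}{i + 1}" for i in range(n_leaves)]

    def clade(names, d):
        # subtree string incl. top edge; tip depth below parent == d
        if len(names) == 1:
            return f"{names[0]}:{d:.8f}"
        half = len(names) // 2
        e = d / 2.0
        return (
            f"({clade(names[:half], d - e)},"
            f"{clade(names[half:], d - e)}):{e:.8f}"
        )

    half = n_leaves // 2
    newick = (
        f"({clade(labels[:half], depth)},{clade(labels[half:], depth)});"
    )
    return PhyloTree.from_newick(newick)


@dataclass
class DomainBlock:
    name: str
    n_codons: int
    omega_by_class: dict[str, float]


@dataclass
class SimulationSpec:
    """Everything needed to evolve one codon alignment, seed included."""

    tree: PhyloTree
    kappa: float
    omega_by_class: dict[str, float]  # {"background": w0[, "foreground": w1]}
    n_codons: int
    seed: int
    freqs: CodonFrequencies | None = None  # default: equal
    foreground: frozenset[str] | None = None  # leaves of the foreground clade
    domain_blocks: list[DomainBlock] | None = None

    def __post_init__(self):
        if self.seed is None:
            raise TpsEvolError("simulation seed is mandatory")
        if self.kappa < 0 or any(
            w < 0 for w in self.omega_by_class.values()
        ):
            raise TpsEvolError("rates must be nonnegative")


def _sample_transitions(rng, P, parent_states):
    """Vectorized child-state draw: one categorical per site."""
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parent_states.size)
    rows = cum[parent_states]
    return (u[:, None] > rows).sum(axis=1)


def simulate_codon_alignment(
    spec: SimulationSpec,
) -> tuple[CodonAlignment, dict]:
    """Evolve codons along the tree; returns the alignment plus the truth.

    Root states are drawn from the equilibrium frequencies; each edge
    applies exp(Q_class * t) of its branch class (foreground = edges whose
    child-side leaves all lie in ``spec.foreground``, including the stem).
    Domain blocks, when given, partition the columns into contiguous
    stretches simulated with their own omega values; the returned truth
    record includes the matching DomainPartition.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = spec.freqs or CodonFrequencies(
        model="equal", pi=np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    )
    tree = spec.tree.derooted()
    nodes = list(tree.tree.postorder_node_iter())
    leafsets = {}
    for n in nodes:
        if n.is_leaf():
            leafsets[id(n)] = frozenset([n.taxon.label])
        else:
            leafsets[id(n)] = frozenset().union(
                *(leafsets[id(c)] for c in n.child_nodes())
            )

    def edge_class(node):
        if spec.foreground and leafsets[id(node)] <= spec.foreground:
            return "foreground"
        return "background"

    blocks = spec.domain_blocks or [
        DomainBlock("all", spec.n_codons, dict(spec.omega_by_class))
    ]
    if sum(b.n_codons for b in blocks) != spec.n_codons:
        raise TpsEvolError("domain blocks do not cover n_codons exactly")

    leaf_states = {}
    col0 = 0
    ranges = {}
    states_by_node: dict[int, np.ndarray] = {}
    for b in blocks:
        ranges[b.name] = (col0, col0 + b.n_codons)
        spectra = {
            cls: SpectralQ(gy94_rate_matrix(spec.kappa, w, freqs))
            for cls, w in b.omega_by_class.items()
        }
        root = tree.tree.seed_node
        root_states = rng.choice(
            len(SENSE_CODONS), size=b.n_codons, p=freqs.pi
        )
        states_by_node = {id(root): root_states}
        for n in tree.tree.preorder_node_iter():
            if n is root:
                continue
            t = n.edge.length or 0.0
            cls = edge_class(n)
            sq = spectra.get(cls) or spectra["background"]
            if t == 0.0:
                child = states_by_node[id(n.parent_node)].copy()
            else:
                child = _sample_transitions(
                    rng, sq.P(t), states_by_node[id(n.parent_node)]
                )
            states_by_node[id(n)] = child
            if n.is_leaf():
                leaf_states.setdefault(n.taxon.label, []).append(child)
        col0 += b.n_codons

    ids = sorted(leaf_states)
    rows = [
        [SENSE_CODONS[s] for block in leaf_states[name] for s in block]
        for name in ids
    ]
    ca = CodonAlignment(ids=ids, rows=rows)
    truth = {
        "kappa": spec.kappa,
        "omega_by_class": dict(spec.omega_by_class),
        "seed": spec.seed,
        "blocks": {
            b.name: dict(b.omega_by_class) for b in blocks
        },
        "partition": DomainPartition.from_ranges(
            {name: rng_ for name, rng_ in ranges.items()},
            note="simulated contiguous blocks",
        ),
    }
    return ca, truth


# --------------------------------------------------------- gene structure

def simulate_gene_models(
    n_per_class: dict[str, int],
    intron_rule: dict[str, int] | None = None,
    seed: int = 0,
    minus_strand_fraction: float = 0.5,
) -> tuple[str, str, dict]:
    """Genome FASTA + GFF3 text realizing prescribed intron counts.

    Exons are 60-300 nt with a multiple-of-3 CDS total, introns 80-2000
    nt; a random fraction of genes land on the minus strand.  Returns
    (fasta_text, gff3_text, truth) where truth maps gene_id to its class
    and intron count.  Byte-identical output for identical inputs+seed.
    """
    intron_rule = DEFAULT_INTRON_RULE if intron_rule is None else intron_rule
    rng = np.random.default_rng(seed)
    sense = [c for c in SENSE_CODONS if c != "ATG"]
    fasta_chunks, gff_lines, truth = [], ["##gff-version 3"], {}
    gene_idx = 0
    for cls in sorted(n_per_class):
        for rep in range(n_per_class[cls]):
            gene_idx += 1
            gid = f"g{gene_idx}_{cls}"
            chrom = f"chr{gene_idx}"
            n_introns = intron_rule[cls]
            n_exons = n_introns + 1
            exon_lens = rng.integers(60, 301, size=n_exons)
            total = int(exon_lens.sum())
            exon_lens[-1] += (3 - total % 3) % 3
            intron_lens = rng.integers(80, 2001, size=n_introns)
            n_codons = int(exon_lens.sum()) // 3
            cds = "ATG" + "".join(
                rng.choice(sense, size=n_codons - 1)
            )
            strand = "-" if rng.random() < minus_strand_fraction else "+"
            pad5 = int(rng.integers(50, 200))
            pos = pad5 + 1
            plus_exons = []
            for k, ln in enumerate(exon_lens):
                plus_exons.append((pos, pos + int(ln) - 1))
                pos += int(ln)
                if k < n_introns:
                    pos += int(intron_lens[k])
            gene_start, gene_end = plus_exons[0][0], plus_exons[-1][1]
            pad3 = int(rng.integers(50, 200))
            genome_len = gene_end + pad3
            genome = rng.choice(list("ACGT"), size=genome_len)
            cds_plus = (
                cds if strand == "+" else _revcomp(cds)
            )
            cursor = 0
            for s, e in plus_exons:
                seg = cds_plus[cursor : cursor + (e - s + 1)]
                genome[s - 1 : e] = list(seg)
                cursor += e - s + 1
            fasta_chunks.append(f">{chrom}\n{''.join(genome)}")
            gff_lines.append(
                f"{chrom}\ttpsevol_sim\tgene\t{gene_start}\t{gene_end}\t.\t"
                f"{strand}\t.\tID={gid}"
            )
            for s, e in plus_exons:
                gff_lines.append(
                    f"{chrom}\ttpsevol_sim\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"Parent={gid}"
                )
                gff_lines.append(
                    f"{chrom}\ttpsevol_sim\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                    f"Parent={gid}"
                )
            truth[gid] = {
                "class": cls,
                "intron_count": n_introns,
                "strand": strand,
                "cds": cds,
            }
    return (
        "\n".join(fasta_chunks) + "\n",
        "\n".join(gff_lines) + "\n",
        truth,
    )


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ------------------------------------------------------------- expression

def simulate_expression_matrix(
    pairs: list[tuple[str, str, str]],
    conditions: list[str],
    noise: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression matrix realizing prescribed fates for duplicate pairs.

    ``pairs`` holds (gene_a, gene_b, fate) with fate one of
    shared_expression, nonfunctionalization_candidate,
    subfunctionalization_candidate, divergent.  After laying down the
    noise-free pattern each call is flipped independently with
    probability ``noise`` (must be < 0.5).
    """
    if not (0.0 <= noise < 0.5):
        raise TpsEvolError("noise must be in [0, 0.5)")
    if len(conditions) < 3:
        raise TpsEvolError("need >= 3 conditions to realize all fates")
    rng = np.random.default_rng(seed)
    genes, calls = [], {}
    nc = len(conditions)
    for ga, gb, fate in pairs:
        on_a = np.ones(nc, dtype=bool)
        on_b = np.ones(nc, dtype=bool)
        if fate == "shared_expression":
            pass
        elif fate == "nonfunctionalization_candidate":
            on_b[:] = False
        elif fate == "subfunctionalization_candidate":
            k = int(rng.integers(1, nc - 1))
            off = rng.choice(nc, size=nc - k, replace=False)
            on_b[off] = False
        elif fate == "divergent":
            # incomparable nonempty proper subsets
            split = int(rng.integers(1, nc - 1))
            on_a[:] = False
            on_b[:] = False
            on_a[:split] = True
            on_b[split:] = True
        else:
            raise TpsEvolError(f"cannot realize fate {fate!r}")
        for g, on in ((ga, on_a), (gb, on_b)):
            flip = rng.random(nc) < noise
            final = on ^ flip
            genes.append(g)
            calls[g] = {
                c: ("expressed" if v else "not_expressed")
                for c, v in zip(conditions, final)
            }
    return ExpressionMatrix(
        genes=genes, conditions=list(conditions), calls=calls
    )
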
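"""Duplicate-pair discovery, mechanism calls and expression-based fates.

Builds a small rooted family tree with two same-species cherries, counts
the minimum number of ancestral genes at the monocot-dicot split, calls
duplication mechanisms from coordinates and a paralogous-block table,
and classifies duplicate fates from a simulated expression matrix.
"""

import pandas as pd

from tpsevol import (
    PhyloTree,
    classify_duplicate_fate,
    classify_duplication_mechanism,
    count_ancestral_lineages,
    find_species_duplicate_pairs,
    simulate_expression_matrix,
)

newick = "(((p1:1,p2:1):1,(a1:0.5,a2:0.5):1.5):1,(r1:1.5,r2:1.5):1.5);"
tree = PhyloTree.from_newick(newick)
species = {
    "p1": "Populus", "p2": "Populus",
    "a1": "Arabidopsis", "a2": "Arabidopsis",
    "r1": "rice", "r2": "rice",
}

pairs, unresolved = find_species_duplicate_pairs(tree, species)
print("same-species cherries (recent duplicate pairs):")
for p in pairs:
    print(f"  {p.gene_a}/{p.gene_b}  ({p.species})")

sides = {"Populus": "dicot", "Arabidopsis": "dicot", "rice": "monocot"}
side_map = {leaf: sides[species[leaf]] for leaf in tree.leaf_ids}
n, groups = count_ancestral_lineages(tree, side_map)
print(f"\nminimum ancestral genes at the monocot-dicot split: {n}")
for g in groups:
    print(f"  group {g['members']} sides={g['sides']}")

gene_table = pd.DataFrame(
    {
        "gene_id": ["p1", "p2", "a1", "a2"],
        "species": ["Populus"] * 2 + ["Arabidopsis"] * 2,
        "side": ["dicot"] * 4,
        "chromosome": ["chr1", "chr1", "chr2", "chr5"],
        "start": [100_000, 150_000, 400_000, 900_000],
        "end": [110_000, 160_000, 410_000, 910_000],
        "strand": ["+"] * 4,
        "class": ["I"] * 4,
    }
)
blocks = [
    {"regionA": ("chr2", 1, 600_000), "regionB": ("chr5", 600_001, 1_200_000)}
]
em = simulate_expression_matrix(
    [
        ("p1", "p2", "shared_expression"),
        ("a1", "a2", "subfunctionalization_candidate"),
    ],
    conditions=["root", "leaf", "stem", "flower", "seed"],
    noise=0.0,
    seed=1,
)

print("\npair   mechanism            fate")
for p in pairs:
    mech = classify_duplication_mechanism(p, gene_table, blocks)
    fate = classify_duplicate_fate(p, em)
    print(f"{p.gene_a}/{p.gene_b}  {mech:<20} {fate}")
# p1/p2 sit 40 kb apart on chr1 -> tandem; a1/a2 fall in paired blocks ->
# whole-genome duplication; their expression patterns give a shared
# (redundant) fate and a subfunctionalization candidate respectively.
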
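"""Classify synthetic TPS-like gene models by intron count.

Class I plant TPS genes carry 16 introns in the protein-coding region,
class II genes carry 2; counting introns over the CDS intervals of a
GFF3 gene model therefore recovers the class assignment.
"""

import os
import tempfile

from tpsevol import GeneRecord, simulate_gene_models
from tpsevol.gene_structure import structure_summary_table
from tpsevol.io import read_gff3_gene_models

fasta, gff3, truth = simulate_gene_models({"I": 3, "II": 3}, seed=42)

with tempfile.TemporaryDirectory() as d:
    path = os.path.join(d, "genes.gff3")
    with open(path, "w") as fh:
        fh.write(gff3)
    models = read_gff3_gene_models(path)

records = [
    GeneRecord(
        gene_id=gid,
        species="synthetic",
        cds=truth[gid]["cds"],
        exons=m["exons"],
        cds_exons=m["cds_exons"],
        strand=m["strand"],
    )
    for gid, m in models.items()
]

table = structure_summary_table(records)
print(table.to_string(index=False))
print()
correct = sum(
    row["inferred_class"] == truth[row["gene_id"]]["class"]
    for _, row in table.iterrows()
)
print(f"{correct}/{len(table)} genes classified back to their generating class.")
# Every gene with 16 introns is called class I and every gene with 2
# introns class II, on both strands — the structural dichotomy is exact.
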
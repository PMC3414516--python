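"""Shared domain types and codon-level plumbing.

Conventions used throughout the package:

* genomic coordinates are 1-based inclusive (GFF3 convention);
* the standard nuclear genetic code with stop codons excluded from the
  61-codon state space;
* terminal stop codons are trimmed at ingestion, internal stops are hard
  errors unless the record is explicitly flagged as a pseudogene;
* ambiguity symbols (N and friends) count as gaps when masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._codons import CODON_TO_AA, GAP_CODON, SENSE_CODONS, STOP_CODONS
from .errors import (
    BackTranslationError,
    EmptyAlignmentError,
    InvalidGeneModelError,
    InvalidSequenceError,
    PrematureStopError,
)

_SENSE_SET = frozenset(SENSE_CODONS)


def translate_cds(cds: str, code: str = "Standard") -> str:
    """Translate a coding sequence, trimming one terminal stop.

    Parameters
    ----------
    cds : str
        Nucleotide sequence, length divisible by 3, ACGT only.
    code : str
        Genetic code name; only the standard nuclear code is supported.

    Returns
    -------
    str
        One amino acid per codon; a single terminal stop is dropped.

    Raises
    ------
    InvalidSequenceError
        Non-ACGT symbol or length not divisible by 3.
    PrematureStopError
        Stop codon before the final position.
    """
    if code != "Standard":
        raise InvalidSequenceError(f"unsupported genetic code: {code!r}")
    s = cds.upper()
    if len(s) % 3 != 0:
        raise InvalidSequenceError(
            f"CDS length {len(s)} not divisible by 3"
        )
    if set(s) - set("ACGT"):
        bad = sorted(set(s) - set("ACGT"))
        raise InvalidSequenceError(f"non-ACGT symbols in CDS: {bad}")
    aas = []
    n_codons = len(s) // 3
    for k in range(n_codons):
        codon = s[3 * k : 3 * k + 3]
        if codon in STOP_CODONS:
            if k == n_codons - 1:
                break  # terminal stop trimmed
            raise PrematureStopError(
                f"internal stop codon {codon} at codon {k + 1}"
            )
        aas.append(CODON_TO_AA[codon])
    return "".join(aas)


def trim_terminal_stop(cds: str) -> str:
    """Return the CDS without its terminal stop codon, if present."""
    s = cds.upper()
    if len(s) >= 3 and len(s) % 3 == 0 and s[-3:] in STOP_CODONS:
        return s[:-3]
    return s


@dataclass
class GeneRecord:
    """One family member: identity, sequences, structure, location.

    ``exons`` (and optional ``cds_exons``) are 1-based inclusive genomic
    intervals in transcription order.  ``taxon_side`` places the species
    on the monocot or dicot side of the angiosperm split.
    """

    gene_id: str
    species: str
    cds: str
    taxon_side: str | None = None  # "monocot" | "dicot" | None
    protein: str | None = None
    chromosome: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None  # "+" | "-"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_exons: list[tuple[int, int]] = field(default_factory=list)
    class_label: str = "unknown"  # "I" | "II" | "unknown"
    pseudogene: bool = False

    def __post_init__(self):
        self.cds = trim_terminal_stop(self.cds)
        if not self.pseudogene:
            prot = translate_cds(self.cds)
            if self.protein is None:
                self.protein = prot
            elif self.protein != prot:
                raise InvalidSequenceError(
                    f"{self.gene_id}: stored protein does not match "
                    "translated CDS"
                )
        _check_intervals(self.exons, self.gene_id, "exon")
        _check_intervals(self.cds_exons, self.gene_id, "CDS")


def _check_intervals(ivals, gene_id, kind):
    for s, e in ivals:
        if s > e:
            raise InvalidGeneModelError(
                f"{gene_id}: {kind} interval ({s},{e}) has start > end"
            )
    by_coord = sorted(ivals)
    for (s1, e1), (s2, e2) in zip(by_coord, by_coord[1:]):
        if s2 <= e1:
            raise InvalidGeneModelError(
                f"{gene_id}: overlapping {kind} intervals "
                f"({s1},{e1}) and ({s2},{e2})"
            )


@dataclass
class ProteinAlignment:
    """Gapped, equal-length amino-acid rows keyed by unique ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(set(self.ids)):
            raise InvalidSequenceError("duplicate ids in alignment")
        if len(self.ids) != len(self.rows):
            raise InvalidSequenceError("ids and rows differ in number")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise InvalidSequenceError("alignment rows differ in length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def subset(self, keep_ids: list[str]) -> "ProteinAlignment":
        return ProteinAlignment(
            ids=list(keep_ids), rows=[self.row(i) for i in keep_ids]
        )


@dataclass
class CodonAlignment:
    """Column-aligned codon cells; each cell a 3-mer or the gap cell '---'.

    Per-row concatenation of the non-gap cells recovers the stop-trimmed
    CDS exactly (the back-translation round trip).
    """

    ids: list[str]
    rows: list[list[str]]

    def __post_init__(self):
        if len(self.ids) != len(set(self.ids)):
            raise InvalidSequenceError("duplicate ids in codon alignment")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise InvalidSequenceError("codon alignment rows differ in length")
        for rid, row in zip(self.ids, self.rows):
            for cell in row:
                if len(cell) != 3:
                    raise InvalidSequenceError(
                        f"{rid}: codon cell {cell!r} is not a triplet"
                    )
                if cell != GAP_CODON and cell in STOP_CODONS:
                    raise InvalidSequenceError(
                        f"{rid}: stop codon {cell} inside alignment"
                    )

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> list[str]:
        return self.rows[self.ids.index(seq_id)]

    def row_cds(self, seq_id: str) -> str:
        return "".join(c for c in self.row(seq_id) if c != GAP_CODON)

    def subset_rows(self, keep_ids: list[str]) -> "CodonAlignment":
        return CodonAlignment(
            ids=list(keep_ids), rows=[list(self.row(i)) for i in keep_ids]
        )

    def subset_columns(self, cols) -> "CodonAlignment":
        cols = sorted(cols)
        return CodonAlignment(
            ids=list(self.ids),
            rows=[[r[c] for c in cols] for r in self.rows],
        )


@dataclass
class DomainPartition:
    """Disjoint codon-column index sets for named domains (TPS, TPP)."""

    domains: dict[str, frozenset[int]]
    note: str = ""

    def __post_init__(self):
        self.domains = {k: frozenset(v) for k, v in self.domains.items()}
        names = list(self.domains)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                if self.domains[names[a]] & self.domains[names[b]]:
                    raise InvalidSequenceError(
                        f"domains {names[a]} and {names[b]} overlap"
                    )

    def validate_for(self, ca: CodonAlignment) -> None:
        for name, cols in self.domains.items():
            if cols and (min(cols) < 0 or max(cols) >= ca.ncol):
                raise InvalidSequenceError(
                    f"domain {name} indexes columns outside the alignment"
                )

    @classmethod
    def from_ranges(cls, ranges: dict[str, tuple[int, int]], note: str = ""):
        """Build from half-open column ranges {name: (start, stop)}."""
        return cls(
            domains={
                name: frozenset(range(s, e)) for name, (s, e) in ranges.items()
            },
            note=note,
        )


EXPRESSION_CALLS = ("expressed", "not_expressed", "missing")


@dataclass
class ExpressionMatrix:
    """Presence/absence calls: gene ids x condition ids.

    Conditions are free-form labels (typically "tissue:treatment").
    ``external_evidence`` carries optional flagged evidence (e.g. EST hits)
    that is kept separate from the assay calls.
    """

    genes: list[str]
    conditions: list[str]
    calls: dict[str, dict[str, str]]  # gene -> condition -> call
    external_evidence: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        for g in self.genes:
            row = self.calls.get(g)
            if row is None or set(row) != set(self.conditions):
                raise InvalidSequenceError(
                    f"expression matrix not rectangular at gene {g}"
                )
            for cond, call in row.items():
                if call not in EXPRESSION_CALLS:
                    raise InvalidSequenceError(
                        f"bad expression call {call!r} for {g}/{cond}"
                    )

    def call(self, gene: str, condition: str) -> str:
        return self.calls[gene][condition]


def back_translate(
    pa: ProteinAlignment, cds_map: dict[str, str]
) -> CodonAlignment:
    """Thread each unaligned CDS through its gapped protein row.

    Every non-gap residue maps to one codon cell; protein gaps map to the
    '---' gap cell.  Raises :class:`BackTranslationError` on length or
    translation mismatches (reported with the failing residue position).
    """
    rows = []
    for seq_id in pa.ids:
        prot_row = pa.row(seq_id)
        if seq_id not in cds_map:
            raise BackTranslationError(f"no CDS provided for {seq_id}")
        cds = trim_terminal_stop(cds_map[seq_id])
        n_res = sum(1 for a in prot_row if a != "-")
        if 3 * n_res != len(cds):
            raise BackTranslationError(
                f"{seq_id}: {n_res} aligned residues need {3 * n_res} nt "
                f"but CDS has {len(cds)}"
            )
        cells = []
        k = 0
        for aa in prot_row:
            if aa == "-":
                cells.append(GAP_CODON)
                continue
            codon = cds[3 * k : 3 * k + 3]
            if codon in STOP_CODONS:
                raise BackTranslationError(
                    f"{seq_id}: internal stop codon at residue {k + 1}"
                )
            if CODON_TO_AA.get(codon) != aa and aa != "X":
                raise BackTranslationError(
                    f"{seq_id}: codon {codon} at residue {k + 1} translates "
                    f"to {CODON_TO_AA.get(codon)}, alignment has {aa}"
                )
            cells.append(codon)
            k += 1
        rows.append(cells)
    return CodonAlignment(ids=list(pa.ids), rows=rows)


def _is_unambiguous(cell: str) -> bool:
    return cell in _SENSE_SET


def mask_gapped_columns(ca: CodonAlignment, policy: str = "complete_deletion"):
    """Apply the chosen gap policy to a codon alignment.

    complete_deletion
        Returns a new :class:`CodonAlignment` without any column containing
        a gap or ambiguous cell.  Raises :class:`EmptyAlignmentError` if
        nothing survives.
    pairwise_deletion
        Returns ``{(id_i, id_j): [columns]}`` for every unordered id pair,
        listing columns where both cells are unambiguous sense codons.
    """
    if policy == "complete_deletion":
        keep = [
            c
            for c in range(ca.ncol)
            if all(_is_unambiguous(row[c]) for row in ca.rows)
        ]
        if not keep:
            raise EmptyAlignmentError(
                "complete deletion removed every column"
            )
        return ca.subset_columns(keep)
    if policy == "pairwise_deletion":
        out = {}
        for a in range(len(ca.ids)):
            for b in range(a + 1, len(ca.ids)):
                ra, rb = ca.rows[a], ca.rows[b]
                out[(ca.ids[a], ca.ids[b])] = [
                    c
                    for c in range(ca.ncol)
                    if _is_unambiguous(ra[c]) and _is_unambiguous(rb[c])
                ]
        return out
    raise ValueError(f"unknown gap policy {policy!r}")
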
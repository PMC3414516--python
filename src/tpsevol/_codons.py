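"""Genetic-code bookkeeping shared by every codon-level stage.

The 61 sense codons of the standard nuclear code are the state space for
all substitution models here; stop codons are excluded and their indices
never appear downstream.  Structural tables (single-step neighbours,
transition flags, synonymy flags) are precomputed once at import.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

_standard = CodonTable.unambiguous_dna_by_name["Standard"]

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61

CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
AA_BY_INDEX: tuple[str, ...] = tuple(CODON_TO_AA[c] for c in SENSE_CODONS)

GAP_CODON = "---"


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def _build_single_step_tables():
    """Index arrays over all ordered sense-codon pairs one mutation apart."""
    src, dst, ts, nonsyn, pos = [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for p in range(3):
            for nt in "ACGT":
                if nt == ci[p]:
                    continue
                cj = ci[:p] + nt + ci[p + 1 :]
                if cj in STOP_CODONS:
                    continue
                j = CODON_INDEX[cj]
                src.append(i)
                dst.append(j)
                ts.append(is_transition(ci[p], nt))
                nonsyn.append(AA_BY_INDEX[i] != AA_BY_INDEX[j])
                pos.append(p)
    return (
        np.asarray(src, dtype=np.intp),
        np.asarray(dst, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(nonsyn, dtype=bool),
        np.asarray(pos, dtype=np.intp),
    )


# ordered single-step sense->sense pairs (stop-avoiding), used by the GY94
# rate matrix and by the NG86/YN00 site and pathway counters
STEP_SRC, STEP_DST, STEP_IS_TS, STEP_IS_NONSYN, STEP_POS = (
    _build_single_step_tables()
)


def codon_diffs(a: str, b: str) -> list[int]:
    """Positions (0-based) at which two codons differ."""
    return [p for p in range(3) if a[p] != b[p]]
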
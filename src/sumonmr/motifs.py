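"""Sequence comparison and SUMO-related motif scanning.

Covers four tasks around SUMO-family sequence analysis:

* pairwise global (Needleman-Wunsch) alignment with BLOSUM62 and affine
  gaps, via Biopython's ``PairwiseAligner``;
* percent identity with an explicit denominator convention (conventions
  differ, and reported identities depend on the choice);
* scanning for the SUMOylation consensus site psi-K-x-E, where psi is a
  bulky hydrophobic residue (L/I/V) and the lysine is the acceptor;
* scanning for SUMO-interacting motifs (SIMs): a short branched-hydrophobic
  core flanked by acidic and/or serine residues.  The SIM definition in the
  literature is prose, not a formula; the rule implemented here is fixed and
  versioned so that scans are reproducible (see ``SIM_RULE_VERSION``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

from .errors import DegenerateDataError

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
PSI_DEFAULT = frozenset("LIV")
PSI_EXTENDED = frozenset("LIVMF")

SIM_HYDROPHOBIC = frozenset("VIL")
SIM_FLANK = frozenset("DES")
SIM_CORE_LEN = 4
SIM_MIN_CORE_HYDROPHOBIC = 3
SIM_FLANK_LEN = 4
SIM_MIN_FLANK_RESIDUES = 2
SIM_RULE_VERSION = "core4-hyd3-flank4-des2/v1"

GAP_OPEN = -10.0
GAP_EXTEND = -0.5


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues) - AA20 - {"X"}
        if bad:
            raise ValueError(f"invalid residue letters: {sorted(bad)}")

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; 1-based inclusive coordinates."""

    kind: str  # "sumo_consensus" | "sim"
    start: int
    end: int
    matched_text: str
    anchor_lysine: int | None = None  # consensus hits only


@dataclass
class Alignment:
    """A pairwise global alignment as two gapped strings of equal length."""

    aligned_a: str
    aligned_b: str
    score: float
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


@lru_cache(maxsize=1)
def _aligner():
    from Bio.Align import PairwiseAligner, substitution_matrices

    return PairwiseAligner(
        mode="global",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=GAP_OPEN,
        extend_gap_score=GAP_EXTEND,
    )


def global_align(a: SequenceRecord, b: SequenceRecord) -> Alignment:
    """Optimal global alignment under BLOSUM62 with affine gaps (open 10, extend 0.5).

    Among co-optimal alignments the aligner's first traversal is taken,
    which prefers matches over gaps; the choice is deterministic.
    """
    if not a.residues or not b.residues:
        raise DegenerateDataError("cannot align an empty sequence")
    aln = _aligner().align(a.residues, b.residues)[0]
    return Alignment(str(aln[0]), str(aln[1]), float(aln.score), a.id, b.id)


def percent_identity(alignment: Alignment, denominator: str = "alignment") -> float:
    """Percent identity of a pairwise alignment.

    ``denominator="alignment"`` divides identical columns by the full
    alignment length including gap columns (the default); ``"shorter"``
    divides by the length of the shorter ungapped sequence.  Report rounded
    values with ``round()``; the raw value is returned.
    """
    if not alignment.aligned_a:
        raise DegenerateDataError("empty alignment")
    ident = sum(
        1 for x, y in zip(alignment.aligned_a, alignment.aligned_b) if x == y and x != "-"
    )
    if denominator == "alignment":
        denom = len(alignment.aligned_a)
    elif denominator == "shorter":
        denom = min(
            len(alignment.aligned_a.replace("-", "")),
            len(alignment.aligned_b.replace("-", "")),
        )
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    return 100.0 * ident / denom


def scan_sumo_consensus(
    seq: SequenceRecord, psi_set: frozenset[str] = PSI_DEFAULT
) -> list[MotifHit]:
    """All psi-K-x-E windows; overlapping hits are each reported.

    The acceptor lysine position (second residue of the motif) is recorded
    as ``anchor_lysine``.
    """
    s = seq.residues
    hits = []
    for i in range(len(s) - 3):
        if s[i] in psi_set and s[i + 1] == "K" and s[i + 3] == "E":
            hits.append(
                MotifHit("sumo_consensus", i + 1, i + 4, s[i : i + 4], anchor_lysine=i + 2)
            )
    return hits


def scan_sim(seq: SequenceRecord) -> list[MotifHit]:
    """Heuristic SIM scan: hydrophobic 4-mer cores with acidic/serine flanks.

    A window of ``SIM_CORE_LEN`` residues qualifies as a core when at least
    ``SIM_MIN_CORE_HYDROPHOBIC`` of its residues are in {V, I, L} and the
    two flanking windows of ``SIM_FLANK_LEN`` residues (clipped at the
    termini) together contain at least ``SIM_MIN_FLANK_RESIDUES`` residues
    from {D, E, S}.  Overlapping qualifying cores are merged into a single
    hit spanning their union.  Rule version: ``SIM_RULE_VERSION``.
    """
    s = seq.residues
    cores = []
    for i in range(len(s) - SIM_CORE_LEN + 1):
        core = s[i : i + SIM_CORE_LEN]
        if sum(c in SIM_HYDROPHOBIC for c in core) < SIM_MIN_CORE_HYDROPHOBIC:
            continue
        left = s[max(0, i - SIM_FLANK_LEN) : i]
        right = s[i + SIM_CORE_LEN : i + SIM_CORE_LEN + SIM_FLANK_LEN]
        if sum(c in SIM_FLANK for c in left + right) >= SIM_MIN_FLANK_RESIDUES:
            cores.append((i + 1, i + SIM_CORE_LEN))  # 1-based inclusive
    merged: list[list[int]] = []
    for start, end in cores:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [
        MotifHit("sim", start, end, s[start - 1 : end]) for start, end in merged
    ]


def k_to_r(seq: SequenceRecord) -> SequenceRecord:
    """Replace every lysine by arginine (the SUMOylation-dead K-to-R construct)."""
    return SequenceRecord(f"{seq.id}_K2R", seq.residues.replace("K", "R"))


def progressive_align3(
    a: SequenceRecord, b: SequenceRecord, c: SequenceRecord
) -> tuple[str, str, str]:
    """Small progressive three-sequence alignment for parity checks.

    Aligns a with b, collapses that alignment to a consensus string (a's
    residue, or b's where a is gapped), aligns c against the consensus, and
    projects the new gaps back into all three rows.  Not a general MSA —
    just enough to sanity-check pairwise identities against a three-way
    layout.
    """
    ab = global_align(a, b)
    consensus = "".join(
        x if x != "-" else y for x, y in zip(ab.aligned_a, ab.aligned_b)
    )
    cons_c = global_align(SequenceRecord("cons", consensus), c)
    row_a, row_b, row_c = [], [], []
    i = 0  # index into the ab alignment / consensus
    for x, y in zip(cons_c.aligned_a, cons_c.aligned_b):
        if x == "-":
            row_a.append("-")
            row_b.append("-")
        else:
            row_a.append(ab.aligned_a[i])
            row_b.append(ab.aligned_b[i])
            i += 1
        row_c.append(y)
    return "".join(row_a), "".join(row_b), "".join(row_c)
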
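"""Protein-level features.

Translation, PEST degron scanning, isoelectric point, N-terminal
hydrophobicity and residue identity, and linear-motif regular-expression
matching.  All residue coordinates are 0-based half-open unless a feature
is defined in the field's 1-based convention (noted where it applies).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Side-chain / terminal pKa values used by the isoelectric-point solver
#: (EMBOSS-style set; swapping the table is a config option, tests pin it).
PKA_TABLE = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,  # acidic side chains (C/Y deprotonate)
    "H": 6.5, "K": 10.8, "R": 12.5,           # basic side chains
}
_ACIDIC = ("Cterm", "C", "D", "E", "Y")
_BASIC = ("Nterm", "H", "K", "R")

#: Packaged linear protein motifs (curated approximations of the published
#: eukaryotic-linear-motif patterns; replaceable via a user regex TSV).
DEFAULT_PROTEIN_MOTIFS: dict[str, str] = {
    "CLV_PCSK_FUR_1": r"R.[RK]R.",
    "LIG_KEPE_1": r"[VILMF]K.EP.{2,4}[ED]",
    "TRG_NLS_Bipartite_1": r"[KR][KR].{7,15}[^DE]((K[RK])|(RK))(([^DE][KR])|([KR][^DE]))[^DE]",
    "TRG_NLS_MonoCore_2": r"[^DE]((K[RK])|(RK))[KR][KR][^DE]",
    "TRG_NLS_MonoExtC_3": r"[^DE]((K[RK])|(RK))[KR].[KR]",
    "TRG_NLS_MonoExtN_4": r"(([PKR].{0,1}[^DE])|([PKR]))((K[RK])|(RK))(([^DE][KR])|([KR][^DE]))[^DE]",
}


class InternalStopError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    transcript_id: str
    aa_sequence: str  # start Met retained, terminal stop dropped


@dataclass(frozen=True)
class PestHit:
    start: int   # 0-based, inclusive of the charged flank residue
    end: int     # half-open, past the closing flank residue
    score: float
    valid: bool  # contains >=1 P, >=1 D/E, >=1 S/T


def translate(cds: str, transcript_id: str = "") -> ProteinRecord:
    """Standard-code translation; the terminal stop codon is dropped."""
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise InternalStopError(f"{transcript_id or cds[:12]}: internal stop codon in CDS")
    return ProteinRecord(transcript_id, aa)


# ---------------------------------------------------------------------------
# PEST regions
# ---------------------------------------------------------------------------

_FLANK = set("KRH")
_HYDIND = {aa: 10.0 * kd + 45.0 for aa, kd in KYTE_DOOLITTLE.items()}


def _pest_score(segment: str) -> float:
    """Score of the internal (flank-free) segment.

    score = 0.55 * (mole percent of D,E,P,S,T) - 0.5 * (mean rescaled
    hydropathy), with hydropathy rescaled to [0, 90] from the
    Kyte-Doolittle index.  Positive, PEST-enriched, hydrophilic stretches
    score high; the conventional "potential" threshold is +5.
    """
    n = len(segment)
    depst = 100.0 * sum(segment.count(a) for a in "DEPST") / n
    hyd = sum(_HYDIND[a] for a in segment) / n
    return 0.55 * depst - 0.5 * hyd


def pest_scan(protein: ProteinRecord, *, threshold: float = 5.0,
              require_valid: bool = True) -> tuple[list[PestHit], int]:
    """Scan for PEST regions between positively charged flanks.

    Candidate regions are maximal K/R/H-free stretches of internal length
    >= 10 bounded by K/R/H (or by the sequence ends, which do not count as
    flanks and therefore do not open/close a candidate).  A candidate is
    *valid* if it contains at least one P, one of D/E and one of S/T.
    ``has_pest`` is 1 iff any valid candidate scores >= ``threshold``.
    """
    seq = protein.aa_sequence
    hits: list[PestHit] = []
    if len(seq) < 12:
        return hits, 0
    flank_pos = [i for i, a in enumerate(seq) if a in _FLANK]
    for a, b in zip(flank_pos[:-1], flank_pos[1:]):
        inner = seq[a + 1:b]
        if len(inner) < 10:
            continue
        valid = ("P" in inner) and any(c in inner for c in "DE") and any(c in inner for c in "ST")
        score = _pest_score(inner)
        hits.append(PestHit(start=a, end=b + 1, score=score, valid=valid))
    has = int(any(h.score >= threshold and (h.valid or not require_valid) for h in hits))
    return hits, has


# ---------------------------------------------------------------------------
# isoelectric point
# ---------------------------------------------------------------------------

def net_charge(protein_counts: Mapping[str, int], ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    ``protein_counts`` maps group name (residue letter or Nterm/Cterm)
    to multiplicity.  Strictly decreasing in pH.
    """
    q = 0.0
    for g in _BASIC:
        n = protein_counts.get(g, 0)
        if n:
            q += n / (1.0 + 10.0 ** (ph - PKA_TABLE[g]))
    for g in _ACIDIC:
        n = protein_counts.get(g, 0)
        if n:
            q -= n / (1.0 + 10.0 ** (PKA_TABLE[g] - ph))
    return q


def _charge_groups(seq: str) -> dict[str, int]:
    counts = {"Nterm": 1, "Cterm": 1}
    for aa in "CDEYHKR":
        n = seq.count(aa)
        if n:
            counts[aa] = n
    return counts


def isoelectric_point(protein: ProteinRecord, tol: float = 1e-6) -> float:
    """pH at which the Henderson-Hasselbalch net charge vanishes.

    Solved by bisection on [0, 14] to |Q| < tol; composition-only, hence
    invariant to residue order.
    """
    counts = _charge_groups(protein.aa_sequence)
    lo, hi = 0.0, 14.0
    q = net_charge(counts, 0.5 * (lo + hi))
    while abs(q) >= tol:
        mid = 0.5 * (lo + hi)
        if q > 0:
            lo = mid
        else:
            hi = mid
        q = net_charge(counts, 0.5 * (lo + hi))
        if hi - lo < 1e-14:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# N-terminal features
# ---------------------------------------------------------------------------

def nterm_hydrophobicity(protein: ProteinRecord) -> float:
    """Mean Kyte-Doolittle hydropathy of residues 2-16 (1-based).

    Shorter proteins use residues 2..end; single-residue proteins are
    missing (NaN).
    """
    seq = protein.aa_sequence
    if len(seq) < 2:
        return float("nan")
    window = seq[1:16]
    return float(np.mean([KYTE_DOOLITTLE[a] for a in window]))


def nterm_residue(protein: ProteinRecord) -> str | None:
    """Second residue of the protein (the N-terminal residue after Met cleavage)."""
    seq = protein.aa_sequence
    return seq[1] if len(seq) >= 2 else None


# ---------------------------------------------------------------------------
# linear motifs
# ---------------------------------------------------------------------------

def compile_motif_regexes(regexes: Mapping[str, str]) -> dict[str, re.Pattern]:
    compiled = {}
    for name, pattern in regexes.items():
        try:
            compiled[name] = re.compile(pattern)
        except re.error as exc:
            raise ValueError(f"invalid regex for motif {name!r}: {exc}") from exc
    return compiled


def linear_motif_indicators(
    protein: ProteinRecord, regexes: Mapping[str, str] | None = None
) -> dict[str, int]:
    """Per motif, indicator of >= 1 regex match anywhere in the sequence."""
    compiled = compile_motif_regexes(regexes or DEFAULT_PROTEIN_MOTIFS)
    return {name: int(rx.search(protein.aa_sequence) is not None) for name, rx in compiled.items()}
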
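"""mRNA secondary-structure proxies around the start codon.

A pluggable energy engine scores 51-nt windows sliding over the 200-nt
span anchored at the start codon (last 100 nt of the 5'UTR + first 100 nt
of the CDS).  The built-in engine is an exact base-pair-maximisation
dynamic program (Watson-Crick + GU wobble, minimum hairpin loop 3,
-1 kcal/mol per pair); a thermodynamic engine via ViennaRNA is an
optional plug-in and is never required by the test suite.

Window centers are positions of the window's central (26th) nucleotide
relative to the first CDS nucleotide (position 0); upstream is negative.
The per-window feature is ``log2(1 + max(0, -MFE))`` so that an
unstructured window maps to 0 and the transform stays monotone.
"""
from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np

from .core_io import TranscriptRecord

_PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

DEFAULT_CENTERS = (-24, 0, 48)
FULL_CENTER_RANGE = tuple(range(-75, 76))
WINDOW_WIDTH = 51
ANCHOR_FLANK = 100  # nt taken on each side of the start codon
MIN_HAIRPIN = 3


class FoldProvider(Protocol):
    name: str

    def energy(self, seq: str) -> float:
        """Minimum free energy in kcal/mol (<= 0; 0 when unstructured)."""


def _pair_ok(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def nussinov_energy(seq: str) -> float:
    """Exact maximum-pairing energy: -1.0 per pair, hairpin loop >= 3."""
    n = len(seq)
    if n < MIN_HAIRPIN + 2:
        return 0.0
    best = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            b = best[i + 1, j]
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                if _pair_ok(seq[i], seq[k]):
                    inner = best[i + 1, k - 1] if k - 1 > i + 1 else 0
                    rest = best[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + inner + rest
                    if cand > b:
                        b = cand
            best[i, j] = b
    return -float(best[0, n - 1])


def nussinov_energies_batch(seqs: Sequence[str]) -> np.ndarray:
    """Vectorised maximum-pairing DP over many equal-length windows."""
    if not seqs:
        return np.zeros(0)
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        return np.array([nussinov_energy(s) for s in seqs])
    m = len(seqs)
    codes = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(m, n)
    lut = np.zeros((256, 256), dtype=bool)
    for a, b in _PAIRABLE:
        lut[ord(a), ord(b)] = True
    best = np.zeros((m, n, n), dtype=np.int32)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            b = best[:, i + 1, j].copy()
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                ok = lut[codes[:, i], codes[:, k]]
                inner = best[:, i + 1, k - 1] if k - 1 > i + 1 else 0
                rest = best[:, k + 1, j] if k + 1 <= j else 0
                np.maximum(b, np.where(ok, 1 + inner + rest, 0), out=b)
            best[:, i, j] = b
    return -best[:, 0, n - 1].astype(float)


@dataclass(frozen=True)
class NussinovProvider:
    name: str = "nussinov"

    def energy(self, seq: str) -> float:
        return nussinov_energy(seq)

    def energies(self, seqs: Sequence[str]) -> np.ndarray:
        return nussinov_energies_batch(list(seqs))


@dataclass(frozen=True)
class ViennaProvider:
    """Thermodynamic MFE via the ViennaRNA ``RNA`` bindings or RNAfold CLI."""

    name: str = "vienna"

    def energy(self, seq: str) -> float:
        rna = seq.upper().replace("T", "U")
        try:
            import RNA  # type: ignore

            _, mfe = RNA.fold(rna)
            return float(min(mfe, 0.0))
        except ImportError:
            out = subprocess.run(
                ["RNAfold", "--noPS"], input=rna + "\n", capture_output=True,
                text=True, check=True,
            ).stdout
            token = out.strip().splitlines()[-1].rsplit("(", 1)[-1].rstrip(")")
            return float(min(float(token), 0.0))

    def energies(self, seqs: Sequence[str]) -> np.ndarray:
        return np.array([self.energy(s) for s in seqs])


def get_provider(name: str) -> FoldProvider:
    if name == "nussinov":
        return NussinovProvider()
    if name in ("vienna", "external"):
        return ViennaProvider()
    raise ValueError(f"unknown fold provider {name!r}")


@dataclass(frozen=True)
class WindowScan:
    transcript_id: str
    centers: tuple[int, ...]
    values: np.ndarray  # log2(1 + max(0, -MFE)) per center


def fold_transform(mfe: float | np.ndarray) -> float | np.ndarray:
    return np.log2(1.0 + np.maximum(0.0, -np.asarray(mfe, dtype=float)))


def anchor_span(record: TranscriptRecord) -> str:
    """Last 100 nt of the 5'UTR + first 101 nt of the CDS.

    With the start codon's first nucleotide at position 0 the window at
    center +75 reaches position +100, the 101st CDS nucleotide; the
    eligibility rule (cds > 100 nt) guarantees it exists.
    """
    return record.utr5[-ANCHOR_FLANK:] + record.cds[:ANCHOR_FLANK + 1]


def eligible_for_scan(record: TranscriptRecord) -> bool:
    return len(record.utr5) > ANCHOR_FLANK and len(record.cds) > ANCHOR_FLANK


def window_sequence(record: TranscriptRecord, center: int, width: int = WINDOW_WIDTH) -> str:
    span = anchor_span(record)
    idx = ANCHOR_FLANK + center  # index of the central nucleotide in the span
    half = width // 2
    lo, hi = idx - half, idx + half + 1
    if lo < 0 or hi > len(span):
        raise ValueError(
            f"window at center {center} does not fit the {len(span)}-nt anchor span"
        )
    return span[lo:hi]


def window_scan(
    record: TranscriptRecord,
    provider: FoldProvider | None = None,
    width: int = WINDOW_WIDTH,
    centers: Sequence[int] = FULL_CENTER_RANGE,
) -> WindowScan:
    """Fold 51-nt windows at the requested centers.

    Requires 5'UTR and CDS both longer than 100 nt (the transcript is
    otherwise excluded upstream and this function raises).
    """
    if not eligible_for_scan(record):
        raise ValueError(
            f"{record.transcript_id}: needs utr5 > {ANCHOR_FLANK} nt and cds > {ANCHOR_FLANK} nt"
        )
    provider = provider or NussinovProvider()
    seqs = [window_sequence(record, c, width) for c in centers]
    if hasattr(provider, "energies"):
        mfes = provider.energies(seqs)
    else:
        mfes = np.array([provider.energy(s) for s in seqs])
    return WindowScan(record.transcript_id, tuple(centers), fold_transform(mfes))


def model_fold_features(scan: WindowScan, centers_subset: Sequence[int] = DEFAULT_CENTERS) -> dict[str, float]:
    """Named feature columns for the design matrix at the chosen centers."""
    out = {}
    for c in centers_subset:
        if c not in scan.centers:
            raise ValueError(f"center {c} not present in scan of {scan.transcript_id}")
        out[f"folding:{c:+d}"] = float(scan.values[scan.centers.index(c)])
    return out
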
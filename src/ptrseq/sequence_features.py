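"""Nucleotide-level features of the PTR design matrix.

Computes codon and amino-acid log2 frequencies, codon-pair principal
components, start/stop codon context encodings, upstream-AUG/uORF flags,
k-mer and motif-site counts, region lengths and GC, 5'-end positional
codon frequencies, and assembles the full genes x features design matrix
(204 columns with the packaged defaults and one-hot context encoding).
"""
from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import folding as _folding
from . import protein_features as _pf
from .core_io import STOP_CODONS, TranscriptRecord, to_rna

#: the 61 sense codons in alphabetical order
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA20 = _pf.AA20

PSEUDOCOUNT = 0.5

# context-window geometry: variable positions around start / stop codons
CONTEXT_POSITIONS = (-6, -5, -4, -3, -2, -1, 3, 4, 5)
#: dropped-reference nucleotides (start: Kozak consensus gccRccAUGG with A
#: at -3; stop: all-A reference, chosen for identifiability only)
START_REFERENCE = {-6: "G", -5: "C", -4: "C", -3: "A", -2: "C", -1: "C", 3: "G", 4: "C", 5: "C"}
STOP_REFERENCE = {p: "A" for p in CONTEXT_POSITIONS}
STOP_ID_REFERENCE = "TAA"


# ---------------------------------------------------------------------------
# codon / amino-acid frequencies
# ---------------------------------------------------------------------------

def _sense_codons(cds: str) -> list[str]:
    """Codons of the CDS excluding the terminal stop."""
    return [cds[i:i + 3] for i in range(0, len(cds) - 3, 3)]


def _log2_freq(counts: np.ndarray, n: int, pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    c = counts.astype(float)
    c[c == 0] = pseudocount
    return np.log2(c / n)


def codon_log2_freq(cds: str, pseudocount: float = PSEUDOCOUNT) -> pd.Series:
    """log2 frequency of each of the 61 sense codons in the CDS.

    The terminal stop is excluded from counts and denominator; zero counts
    are replaced by ``pseudocount`` before dividing so absent codons stay
    finite.
    """
    codons = _sense_codons(cds)
    if len(codons) <= 1:
        warnings.warn(f"CDS with only {len(codons)} sense codon(s)", stacklevel=2)
    counts = np.zeros(61)
    for c in codons:
        counts[_CODON_INDEX[c]] += 1
    return pd.Series(_log2_freq(counts, len(codons), pseudocount),
                     index=[f"codon:{c}" for c in SENSE_CODONS])


def aa_log2_freq(cds: str, pseudocount: float = PSEUDOCOUNT) -> pd.Series:
    """log2 frequency of the 20 amino acids of the translated CDS."""
    aa = _pf.translate(cds).aa_sequence
    counts = np.array([aa.count(a) for a in AA20], dtype=float)
    return pd.Series(_log2_freq(counts, len(aa), pseudocount),
                     index=[f"aa:{a}" for a in AA20])


def codon_pair_pcs(cds_list: Sequence[str], n_components: int = 2) -> np.ndarray:
    """Top principal-component scores of the 61x61 ordered codon-pair
    frequency matrix (consecutive sense-codon pairs; denominator = number
    of pairs).  Columns are centred; each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    if len(cds_list) < 3:
        raise ValueError("need at least 3 CDSs for codon-pair PCA")
    pair_index = {p: i for i, p in enumerate(itertools.product(SENSE_CODONS, SENSE_CODONS))}
    X = np.zeros((len(cds_list), len(pair_index)))
    for g, cds in enumerate(cds_list):
        codons = _sense_codons(cds)
        n_pairs = len(codons) - 1
        if n_pairs < 1:
            continue
        for a, b in zip(codons[:-1], codons[1:]):
            X[g, pair_index[(a, b)]] += 1.0
        X[g] /= n_pairs
    X -= X.mean(axis=0)
    if not np.any(X):
        warnings.warn("codon-pair matrix degenerate (all genes identical)", stacklevel=2)
        return np.zeros((len(cds_list), n_components))
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(X)
    for k in range(scores.shape[1]):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, k] = -scores[:, k]
    return scores


# ---------------------------------------------------------------------------
# start / stop codon context
# ---------------------------------------------------------------------------

def _context_letters(record: TranscriptRecord) -> tuple[dict[int, str], dict[int, str], str]:
    """Observed nucleotides at the variable start/stop context positions.

    Start positions -6..-1 index into the 5'UTR tail, +3..+5 into the CDS
    (position 0 = A of AUG).  Stop positions -6..-1 are the last CDS
    nucleotides before the stop codon, +3..+5 the first 3'UTR nucleotides
    (position 0 = first nucleotide of the stop).  A 3'UTR shorter than 3 nt
    pads missing downstream positions with the reference letter.
    """
    u5, cds, u3 = record.utr5, record.cds, record.utr3
    start = {}
    for p in CONTEXT_POSITIONS:
        start[p] = u5[len(u5) + p] if p < 0 else cds[p]
    stop0 = len(cds) - 3
    stop = {}
    for p in CONTEXT_POSITIONS:
        if p < 0:
            stop[p] = cds[stop0 + p]
        else:
            k = p - 3
            stop[p] = u3[k] if k < len(u3) else STOP_REFERENCE[p]
    return start, stop, cds[-3:]


def context_feature_names(encoding: Literal["onehot", "dropped"] = "onehot") -> tuple[list[str], list[str]]:
    kozak, stopc = [], []
    for p in CONTEXT_POSITIONS:
        for nt in "ACGT":
            if encoding == "dropped" and nt == START_REFERENCE[p]:
                continue
            kozak.append(f"kozak:{p:+d}:{to_rna(nt)}")
    for p in CONTEXT_POSITIONS:
        for nt in "ACGT":
            if encoding == "dropped" and nt == STOP_REFERENCE[p]:
                continue
            stopc.append(f"stop_context:{p:+d}:{to_rna(nt)}")
    stops = STOP_CODONS if encoding == "onehot" else tuple(s for s in STOP_CODONS if s != STOP_ID_REFERENCE)
    stopc += [f"stop_context:stop:{to_rna(s)}" for s in stops]
    return kozak, stopc


def context_features(
    record: TranscriptRecord, encoding: Literal["onehot", "dropped"] = "onehot"
) -> dict[str, int]:
    """Indicator encoding of the [-6,+6] nt windows around start and stop.

    ``onehot`` emits 4 indicators per position plus 3 stop identities
    (36 + 39 columns, the canonical bookkeeping); ``dropped`` omits the
    reference nucleotide per position and the TAA stop (27 + 29 columns,
    identifiable alongside an intercept).
    """
    if len(record.utr5) < 6 or len(record.cds) < 12:
        raise ValueError(f"{record.transcript_id}: context needs utr5 >= 6 nt and cds >= 12 nt")
    start, stop, stop_codon = _context_letters(record)
    kozak_names, stop_names = context_feature_names(encoding)
    out = {}
    for name in kozak_names:
        _, pos, nt = name.split(":")
        out[name] = int(start[int(pos)] == nt.replace("U", "T"))
    for name in stop_names:
        _, pos, nt = name.split(":")
        if pos == "stop":
            out[name] = int(stop_codon == nt.replace("U", "T"))
        else:
            out[name] = int(stop[int(pos)] == nt.replace("U", "T"))
    return out


# ---------------------------------------------------------------------------
# upstream AUGs and uORFs
# ---------------------------------------------------------------------------

def upstream_aug_features(record: TranscriptRecord) -> dict[str, int]:
    """Scan the 5'UTR for AUG triplets.

    The reading frame of a uAUG at offset p is ``(len(utr5) - p) mod 3``
    (0 = in frame with the main ORF).  A uORF requires an in-frame stop
    codon, relative to that uAUG, lying entirely within the 5'UTR.
    """
    u5 = record.utr5
    n = len(u5)
    out_of_frame = in_frame = uorf = n_aug = 0
    for p in range(n - 2):
        if u5[p:p + 3] != "ATG":
            continue
        n_aug += 1
        if (n - p) % 3 != 0:
            out_of_frame = 1
        else:
            in_frame = 1
        for q in range(p + 3, n - 2, 3):
            if u5[q:q + 3] in STOP_CODONS:
                uorf = 1
                break
    return {
        "out_of_frame_uAUG": out_of_frame,
        "in_frame_uAUG": in_frame,
        "uORF": uorf,
        "n_uAUG": n_aug,
    }


# ---------------------------------------------------------------------------
# k-mers and motif sites
# ---------------------------------------------------------------------------

def kmer_counts(seq: str, k_min: int = 3, k_max: int = 8) -> dict[str, int]:
    """Overlapping k-mer occurrence counts for every k in [k_min, k_max].

    Single-stranded (mRNA sense only); no reverse-complement folding.
    """
    if not (3 <= k_min <= k_max <= 8):
        raise ValueError("k range must satisfy 3 <= k_min <= k_max <= 8")
    counts: Counter[str] = Counter()
    for k in range(k_min, k_max + 1):
        for i in range(len(seq) - k + 1):
            counts[seq[i:i + k]] += 1
    return dict(counts)


def count_occurrences(seq: str, motif: str) -> int:
    """Overlapping exact occurrences of ``motif`` in ``seq``."""
    n, k = len(seq), len(motif)
    return sum(1 for i in range(n - k + 1) if seq[i:i + k] == motif)


@dataclass(frozen=True)
class MotifSpec:
    """One motif column of the design matrix.

    ``motif`` is stored in the alphabet it is matched in (DNA for
    nucleotide motifs, one-letter residues for amino-acid motifs);
    reporting uses the RNA alphabet for nucleotide motifs.
    """

    motif: str
    region: Literal["utr5", "cds", "utr3"]
    encoding: Literal["count", "binary"] = "count"
    alphabet: Literal["nt", "aa"] = "nt"
    synthetic: bool = False

    @property
    def label(self) -> str:
        shown = to_rna(self.motif) if self.alphabet == "nt" else self.motif
        return f"{self.region}_motif:{shown}"


def _dna(m: str) -> str:
    return m.upper().replace("U", "T")


# Packaged default motif rosters.  Motifs reported in the source study's
# running text are included verbatim (polyadenylation signal AAUAAA,
# AU-rich elements UAUUUAU/AUUUUUA, the Pumilio site UGUAAAUA, the
# reporter-validated 5'UTR elements CUGUCCU and UUCCG, etc.).  The full
# published rosters are only available as figure panels, so the remaining
# slots up to the canonical sizes (25 5'UTR / 20 3'UTR / 3 CDS columns)
# are filled with synthetic placeholder k-mers flagged ``synthetic=True``;
# replace them with a user motif TSV for real analyses.
DEFAULT_UTR5_MOTIFS: tuple[MotifSpec, ...] = (
    MotifSpec("ATG", "utr5", "binary"),  # out-of-frame uAUG presence
    *(MotifSpec(_dna(m), "utr5") for m in
      ("CUGUCCU", "UUCCG", "CCCACCC", "GGCCCCUG", "AGCGGAA", "GCCGCC")),
    *(MotifSpec(_dna(m), "utr5", synthetic=True) for m in
      ("CGGCGG", "AGGAGG", "UCCUCC", "CGCCGC", "GGCGGC", "CCGCCG",
       "AGGCGG", "CGGAGG", "GCGGCG", "CCUCCU", "UCCGCC", "GGAGGC",
       "CGCGCG", "AUCGCA", "UGCGUA", "CAGUCG", "GUCAGU", "ACGUAC")),
)
DEFAULT_UTR3_MOTIFS: tuple[MotifSpec, ...] = (
    MotifSpec("AATAAA", "utr3", "binary"),
    *(MotifSpec(_dna(m), "utr3") for m in
      ("UAUUUAU", "AUUUUUA", "UGUAAAUA", "ACCAAA", "CCAAAG", "CUCAGG",
       "GGGCUGCG", "GGAGCC", "GGCCCUG", "UUCUGAG", "ACACUA")),
    *(MotifSpec(_dna(m), "utr3", synthetic=True) for m in
      ("UUUGUUU", "AAUGCAU", "CAUCAUC", "UGGACUU", "GCAUGCA", "UUCAAGU",
       "ACGUCAU", "UGUCGUA")),
)
DEFAULT_CDS_MOTIFS: tuple[MotifSpec, ...] = (
    MotifSpec("CG", "cds", "count", "aa"),
    MotifSpec("KRR", "cds", "count", "aa"),
    MotifSpec("NS", "cds", "count", "aa"),
)


def motif_site_features(
    record: TranscriptRecord, motifs: Sequence[MotifSpec],
    protein: _pf.ProteinRecord | None = None,
) -> dict[str, float]:
    """Per motif: overlapping site count in its region, or a presence
    indicator for the binary-encoded motifs (out-of-frame uAUG in the
    5'UTR; the polyadenylation signal in the 3'UTR)."""
    out: dict[str, float] = {}
    for spec in motifs:
        if spec.alphabet == "aa":
            if protein is None:
                protein = _pf.translate(record.cds, record.transcript_id)
            seq = protein.aa_sequence
        else:
            seq = getattr(record, spec.region)
            if not set(spec.motif) <= set("ACGT"):
                raise ValueError(f"motif {spec.motif!r} has invalid nucleotide alphabet")
        if spec.motif == "ATG" and spec.region == "utr5" and spec.encoding == "binary":
            out[spec.label] = upstream_aug_features(record)["out_of_frame_uAUG"]
        elif spec.encoding == "binary":
            out[spec.label] = int(count_occurrences(seq, spec.motif) > 0)
        else:
            out[spec.label] = count_occurrences(seq, spec.motif)
    return out


# ---------------------------------------------------------------------------
# region basics and 5' end positional codon usage
# ---------------------------------------------------------------------------

def region_basics(record: TranscriptRecord) -> dict[str, float]:
    out = {}
    for region in ("utr5", "cds", "utr3"):
        seq = getattr(record, region)
        out[f"length:{region}"] = float(np.log2(len(seq)))
        out[f"gc:{region}"] = (seq.count("G") + seq.count("C")) / len(seq)
    return out


N_WINDOWS_5P = 11
WINDOW_CODONS = 15
MIN_CDS_NT_5P = 461  # CDS must be longer than 460 nt


def cds_5prime_window_freqs(
    cds_map: Mapping[str, str], pseudocount: float = PSEUDOCOUNT
) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-window codon log2 frequencies near the CDS 5' end.

    Windows w = 1..11 are non-overlapping 15-codon stretches starting at
    codon 2 (codons 2-16, 17-31, ...).  Only transcripts with CDS longer
    than 460 nt are included; shorter ones are reported as excluded.

    Returns (tensor genes x 11 x 61, included ids, excluded ids).
    """
    included, excluded = [], []
    rows = []
    for tid, cds in cds_map.items():
        if len(cds) < MIN_CDS_NT_5P:
            excluded.append(tid)
            continue
        codons = _sense_codons(cds)
        win = np.zeros((N_WINDOWS_5P, 61))
        for w in range(N_WINDOWS_5P):
            chunk = codons[1 + w * WINDOW_CODONS: 1 + (w + 1) * WINDOW_CODONS]
            counts = np.zeros(61)
            for c in chunk:
                counts[_CODON_INDEX[c]] += 1
            win[w] = _log2_freq(counts, len(chunk), pseudocount)
        included.append(tid)
        rows.append(win)
    tensor = np.stack(rows) if rows else np.zeros((0, N_WINDOWS_5P, 61))
    return tensor, included, excluded


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureOptions:
    context_encoding: Literal["onehot", "dropped"] = "onehot"
    include_folding: bool = True
    fold_centers: tuple[int, ...] = _folding.DEFAULT_CENTERS
    fold_provider: str = "nussinov"
    utr5_motifs: tuple[MotifSpec, ...] = DEFAULT_UTR5_MOTIFS
    utr3_motifs: tuple[MotifSpec, ...] = DEFAULT_UTR3_MOTIFS
    cds_motifs: tuple[MotifSpec, ...] = DEFAULT_CDS_MOTIFS
    protein_motifs: tuple[tuple[str, str], ...] = tuple(_pf.DEFAULT_PROTEIN_MOTIFS.items())
    include_nterm_residue: bool = False
    pseudocount: float = PSEUDOCOUNT


@dataclass(frozen=True)
class FeatureMatrix:
    """genes x named features with per-column group labels and scale notes."""

    values: pd.DataFrame
    groups: pd.Series   # column -> group label
    scale: pd.Series    # column -> 'log2' | 'indicator' | 'count' | 'real'
    dropped: tuple[tuple[str, str], ...] = ()  # (transcript_id, reason)

    def columns_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def assemble_feature_matrix(
    records: Sequence[TranscriptRecord],
    options: FeatureOptions = FeatureOptions(),
) -> FeatureMatrix:
    """Column-bind all feature groups in a fixed documented order.

    Order: codon (61), kozak (36/27), stop_context (39/29), length (3),
    gc (3), utr3_motif (20), utr5_motif (25), cds_motif (3),
    protein_linear_motif (6), folding (3), codon_pair_pc (2), pest (1),
    pi (1), nterm_hydrophobicity (1) -- 204 columns with the one-hot
    context encoding and packaged motif lists.  Records failing any
    precondition (e.g. too-short regions for the folding anchor) are
    dropped and reported in ``dropped``.
    """
    if not records:
        raise ValueError("empty record set")
    usable: list[TranscriptRecord] = []
    dropped: list[tuple[str, str]] = []
    for rec in records:
        if len(rec.utr5) < 6 or len(rec.cds) < 12:
            dropped.append((rec.transcript_id, "context window preconditions"))
        elif options.include_folding and not _folding.eligible_for_scan(rec):
            dropped.append((rec.transcript_id, "folding anchor needs utr5>100 and cds>100"))
        else:
            usable.append(rec)
    if not usable:
        raise ValueError("no usable records after precondition filtering")

    ids = [r.transcript_id for r in usable]
    proteins = {r.transcript_id: _pf.translate(r.cds, r.transcript_id) for r in usable}

    blocks: list[pd.DataFrame] = []
    groups: dict[str, str] = {}
    scale: dict[str, str] = {}

    def add_block(frame: pd.DataFrame, group: str, note: str) -> None:
        blocks.append(frame)
        for c in frame.columns:
            groups[c] = group
            scale[c] = note

    add_block(pd.DataFrame(
        [codon_log2_freq(r.cds, options.pseudocount) for r in usable], index=ids),
        "codon", "log2")

    ctx = pd.DataFrame(
        [context_features(r, options.context_encoding) for r in usable], index=ids)
    kozak_names, stop_names = context_feature_names(options.context_encoding)
    add_block(ctx[kozak_names], "kozak", "indicator")
    add_block(ctx[stop_names], "stop_context", "indicator")

    basics = pd.DataFrame([region_basics(r) for r in usable], index=ids)
    add_block(basics[[f"length:{x}" for x in ("cds", "utr5", "utr3")]], "length", "log2")
    add_block(basics[[f"gc:{x}" for x in ("cds", "utr5", "utr3")]], "gc", "real")

    add_block(pd.DataFrame(
        [motif_site_features(r, options.utr3_motifs) for r in usable], index=ids),
        "utr3_motif", "count")
    add_block(pd.DataFrame(
        [motif_site_features(r, options.utr5_motifs) for r in usable], index=ids),
        "utr5_motif", "count")
    add_block(pd.DataFrame(
        [motif_site_features(r, options.cds_motifs, proteins[r.transcript_id]) for r in usable],
        index=ids), "cds_motif", "count")

    prot_regex = dict(options.protein_motifs)
    add_block(pd.DataFrame(
        [{f"protein_motif:{k}": v
          for k, v in _pf.linear_motif_indicators(proteins[r.transcript_id], prot_regex).items()}
         for r in usable], index=ids), "protein_linear_motif", "indicator")

    if options.include_folding:
        provider = _folding.get_provider(options.fold_provider)
        fold_rows = []
        if hasattr(provider, "energies"):
            seqs, order = [], []
            for r in usable:
                for c in options.fold_centers:
                    seqs.append(_folding.window_sequence(r, c))
                    order.append((r.transcript_id, c))
            vals = _folding.fold_transform(provider.energies(seqs))
            frame = pd.DataFrame(
                {f"folding:{c:+d}": vals[[i for i, (_, cc) in enumerate(order) if cc == c]]
                 for c in options.fold_centers}, index=ids)
        else:
            for r in usable:
                scan = _folding.window_scan(r, provider, centers=options.fold_centers)
                fold_rows.append(_folding.model_fold_features(scan, options.fold_centers))
            frame = pd.DataFrame(fold_rows, index=ids)
        add_block(frame, "folding", "real")

    pcs = codon_pair_pcs([r.cds for r in usable])
    add_block(pd.DataFrame(pcs, index=ids, columns=["codon_pair_pc:1", "codon_pair_pc:2"]),
              "codon_pair_pc", "real")

    add_block(pd.DataFrame(
        {"pest": [float(_pf.pest_scan(proteins[r.transcript_id])[1]) for r in usable]},
        index=ids), "pest", "indicator")
    add_block(pd.DataFrame(
        {"isoelectric_point": [_pf.isoelectric_point(proteins[r.transcript_id]) for r in usable]},
        index=ids), "pi", "real")
    add_block(pd.DataFrame(
        {"nterm_hydrophobicity": [_pf.nterm_hydrophobicity(proteins[r.transcript_id]) for r in usable]},
        index=ids), "nterm_hydrophobicity", "real")

    if options.include_nterm_residue:
        res = pd.Series([_pf.nterm_residue(proteins[r.transcript_id]) or "?" for r in usable], index=ids)
        onehot = pd.get_dummies(res, prefix="nterm_residue", prefix_sep=":").astype(float)
        add_block(onehot, "nterm_residue", "indicator")

    values = pd.concat(blocks, axis=1)
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"missing entries in feature columns: {bad[:5]}")
    return FeatureMatrix(
        values=values,
        groups=pd.Series(groups).reindex(values.columns),
        scale=pd.Series(scale).reindex(values.columns),
        dropped=tuple(dropped),
    )
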
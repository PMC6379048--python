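"""Domain types, validation and TSV/FASTA readers/writers.

All coordinates are 0-based half-open.  RNA input (``U``) is canonicalised
to the DNA alphabet internally; motif *reporting* converts back to the RNA
alphabet.  The missing-data sentinel in every TSV is ``"NA"``.
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

NUCLEOTIDES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

#: minimum UTR length for a transcript to enter the analysis (strictly
#: longer than 6 nt on both sides).
MIN_UTR_LEN = 7

_VALID_RE = re.compile(r"^[ACGT]*$")


class FormatError(ValueError):
    """A required column or field is missing or malformed."""


class DuplicateKeyError(ValueError):
    """Duplicate identifier in a table keyed by unique ids."""


class ValidationError(ValueError):
    """Sequence content violates the transcript invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptRecord:
    """One gene's major-isoform region sequences (DNA alphabet, uppercase)."""

    transcript_id: str
    gene_id: str
    utr5: str
    cds: str
    utr3: str


@dataclass(frozen=True)
class SampleSheet:
    """sample_id -> (tissue, replicate_index) assignment."""

    frame: pd.DataFrame  # columns: sample_id, tissue, replicate_index

    def __post_init__(self) -> None:
        need = {"sample_id", "tissue", "replicate_index"}
        if not need.issubset(self.frame.columns):
            raise FormatError(
                f"sample sheet missing columns: {sorted(need - set(self.frame.columns))}"
            )
        if self.frame["sample_id"].duplicated().any():
            raise DuplicateKeyError("duplicate sample_id in sample sheet")
        pairs = self.frame[["tissue", "replicate_index"]]
        if pairs.duplicated().any():
            raise DuplicateKeyError("duplicate (tissue, replicate_index) pair")

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.frame["tissue"]))

    def samples_for(self, tissue: str) -> list[str]:
        return list(self.frame.loc[self.frame["tissue"] == tissue, "sample_id"])


@dataclass(frozen=True)
class CountTable:
    """Non-negative integer read counts, rows transcripts x columns samples."""

    values: pd.DataFrame
    kind: str  # 'exonic' or 'intronic'

    def __post_init__(self) -> None:
        if self.kind not in ("exonic", "intronic"):
            raise FormatError(f"count table kind must be exonic/intronic, got {self.kind!r}")
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise DuplicateKeyError(f"duplicate labels in {self.kind} count table")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError(f"negative entries in {self.kind} count table")


@dataclass(frozen=True)
class IbaqTable:
    """Protein iBAQ intensities, rows transcripts x columns tissues.

    Zeros are permitted on read; they become missing downstream.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("negative iBAQ intensity")


@dataclass(frozen=True)
class ConservationTrack:
    """Per-base conservation scores in [0,1].

    Stored long-form: columns transcript_id, region, position, score.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"transcript_id", "region", "position", "score"}
        if not need.issubset(self.frame.columns):
            raise FormatError(f"conservation track missing columns: {sorted(need - set(self.frame.columns))}")
        s = self.frame["score"].to_numpy(dtype=float)
        if ((s < 0) | (s > 1)).any():
            raise ValidationError("conservation scores must lie in [0,1]")

    def scores(self, transcript_id: str, region: str) -> np.ndarray:
        sub = self.frame[
            (self.frame["transcript_id"] == transcript_id) & (self.frame["region"] == region)
        ]
        sub = sub.sort_values("position")
        out = np.full(int(sub["position"].max()) + 1 if len(sub) else 0, np.nan)
        out[sub["position"].to_numpy(int)] = sub["score"].to_numpy(float)
        return out


@dataclass(frozen=True)
class ValidationReport:
    record_id: str
    failures: tuple[tuple[str, str], ...] = ()  # (rule_id, message)

    @property
    def ok(self) -> bool:
        return not self.failures

    def rule_ids(self) -> tuple[str, ...]:
        return tuple(r for r, _ in self.failures)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def canonicalize(seq: str) -> str:
    """Uppercase and map U -> T."""
    return seq.upper().replace("U", "T")


def validate_transcript(record: TranscriptRecord) -> ValidationReport:
    """Report every violated transcript rule; never raises.

    Rules, in fixed order: alphabet per region, CDS frame, start codon,
    stop codon, internal in-frame stop, UTR length filter (>6 nt).
    """
    failures: list[tuple[str, str]] = []
    for region in ("utr5", "cds", "utr3"):
        seq = getattr(record, region, "") or ""
        if not isinstance(seq, str) or not _VALID_RE.match(seq):
            bad = next(
                (i for i, ch in enumerate(seq) if ch not in NUCLEOTIDES),
                None,
            ) if isinstance(seq, str) else None
            failures.append(
                (f"{region}_alphabet",
                 f"{record.transcript_id}: {region} has non-ACGT character"
                 + (f" at position {bad}" if bad is not None else ""))
            )
    cds = record.cds if isinstance(record.cds, str) else ""
    if len(cds) % 3 != 0:
        failures.append(("cds_frame", f"{record.transcript_id}: cds not divisible by 3"))
    if len(cds) >= 3:
        if cds[:3] != START_CODON:
            failures.append(("cds_start", f"{record.transcript_id}: cds does not start with ATG"))
        if len(cds) % 3 == 0 and cds[-3:] not in STOP_CODONS:
            failures.append(("cds_stop", f"{record.transcript_id}: cds does not end with a stop codon"))
        if len(cds) % 3 == 0:
            internal = [cds[i:i + 3] for i in range(0, len(cds) - 3, 3)]
            if any(c in STOP_CODONS for c in internal):
                failures.append(("internal_stop", f"{record.transcript_id}: in-frame internal stop codon"))
    else:
        failures.append(("cds_start", f"{record.transcript_id}: cds shorter than one codon"))
    utr5 = record.utr5 if isinstance(record.utr5, str) else ""
    utr3 = record.utr3 if isinstance(record.utr3, str) else ""
    if len(utr5) < MIN_UTR_LEN:
        failures.append(("utr5_too_short", f"{record.transcript_id}: utr5 length {len(utr5)} <= 6"))
    if len(utr3) < MIN_UTR_LEN:
        failures.append(("utr3_too_short", f"{record.transcript_id}: utr3 length {len(utr3)} <= 6"))
    return ValidationReport(record.transcript_id, tuple(failures))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TRANSCRIPT_COLUMNS = ("transcript_id", "gene_id", "utr5", "cds", "utr3")


def read_transcript_table(path: str | Path, *, strict: bool = True) -> list[TranscriptRecord]:
    """Read transcripts.tsv into validated records.

    With ``strict`` (default) any record failing :func:`validate_transcript`
    raises; otherwise invalid records are silently dropped.
    """
    df = read_table(path)
    missing = [c for c in _TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"transcript table missing column(s): {missing}")
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise DuplicateKeyError(f"duplicate transcript_id: {dups[:5]}")
    records: list[TranscriptRecord] = []
    for row in df.itertuples(index=False):
        rec = TranscriptRecord(
            transcript_id=str(row.transcript_id),
            gene_id=str(row.gene_id),
            utr5=canonicalize(str(row.utr5)),
            cds=canonicalize(str(row.cds)),
            utr3=canonicalize(str(row.utr3)),
        )
        report = validate_transcript(rec)
        if not report.ok:
            if strict:
                raise ValidationError(
                    "; ".join(msg for _, msg in report.failures)
                )
            continue
        records.append(rec)
    return records


def read_transcript_fastas(
    utr5_path: str | Path, cds_path: str | Path, utr3_path: str | Path,
    *, gene_map: Mapping[str, str] | None = None, strict: bool = True,
) -> list[TranscriptRecord]:
    """Assemble records from three per-region FASTA files keyed by transcript_id."""
    regions = {}
    for name, p in (("utr5", utr5_path), ("cds", cds_path), ("utr3", utr3_path)):
        seqs = {}
        for entry in SeqIO.parse(str(p), "fasta"):
            if entry.id in seqs:
                raise DuplicateKeyError(f"duplicate id {entry.id} in {name} fasta")
            seqs[entry.id] = canonicalize(str(entry.seq))
        regions[name] = seqs
    ids = sorted(set(regions["utr5"]) & set(regions["cds"]) & set(regions["utr3"]))
    rows = pd.DataFrame(
        {
            "transcript_id": ids,
            "gene_id": [gene_map.get(t, t) if gene_map else t for t in ids],
            "utr5": [regions["utr5"][t] for t in ids],
            "cds": [regions["cds"][t] for t in ids],
            "utr3": [regions["utr3"][t] for t in ids],
        }
    )
    buf = io.StringIO()
    write_table(rows, buf)
    buf.seek(0)
    return read_transcript_table(buf, strict=strict)


def write_table(rows: pd.DataFrame, path) -> None:
    """TSV writer: UTF-8, '.' decimal, missing encoded as NA, 12 significant digits."""
    rows.to_csv(path, sep="\t", index=isinstance(rows.index, pd.Index) and rows.index.name is not None,
                na_rep="NA", float_format="%.12g")


def read_table(path, **kwargs) -> pd.DataFrame:
    """TSV reader matching :func:`write_table` conventions."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, **kwargs)


def write_matrix(mat: pd.DataFrame, path, index_name: str = "transcript_id") -> None:
    out = mat.copy()
    out.index.name = index_name
    write_table(out, path)


def read_matrix(path, index_col: str = "transcript_id") -> pd.DataFrame:
    return read_table(path).set_index(index_col)


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(read_table(path))


def read_count_table(path, kind: str) -> CountTable:
    df = read_matrix(path)
    return CountTable(df.astype(np.int64), kind)


def read_ibaq_table(path) -> IbaqTable:
    return IbaqTable(read_matrix(path).astype(float))


def read_conservation(path) -> ConservationTrack:
    return ConservationTrack(read_table(path))


def transcripts_to_frame(records: Iterable[TranscriptRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.transcript_id, r.gene_id, r.utr5, r.cds, r.utr3) for r in records],
        columns=list(_TRANSCRIPT_COLUMNS),
    )


def to_rna(seq: str) -> str:
    """DNA -> RNA alphabet for motif reporting (ATG -> AUG)."""
    return seq.upper().replace("T", "U")
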
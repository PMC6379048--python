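"""From raw count and iBAQ tables to tissue-level log10 mRNA, protein and
PTR matrices.

The mature-mRNA signal per sample is the exonic read density minus the
intronic read density (reads per kilobase), correcting for unspliced
pre-mRNA.  Samples are then scaled by median-of-ratios size factors,
censored below 10 reads/kb, summarised over technical replicates by the
median, and log10-transformed.  Protein intensities are log10 iBAQ with
zeros treated as missing and per-tissue medians aligned to the global
median.  The PTR matrix is the elementwise difference of the two log10
matrices.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CountTable, IbaqTable, SampleSheet

READS_PER_KB_CUTOFF = 10.0


class LabelMismatchError(ValueError):
    pass


def _check_labels(a: pd.Index, b: pd.Index, what: str) -> None:
    if not a.equals(b):
        sym = sorted(set(a).symmetric_difference(set(b)))
        raise LabelMismatchError(f"{what} labels differ; symmetric difference: {sym[:10]}")


# ---------------------------------------------------------------------------
# protein side
# ---------------------------------------------------------------------------

def summarize_protein(ibaq: IbaqTable) -> pd.DataFrame:
    """log10 iBAQ with zeros as missing and tissue medians aligned.

    Each tissue gets an additive constant c_t = global median - tissue
    median (on the log scale), so that afterwards every tissue's median
    equals the global median.  Idempotent.  An all-missing tissue gets
    constant 0 with a warning.
    """
    vals = ibaq.values.astype(float).copy()
    vals[vals == 0.0] = np.nan
    log = np.log10(vals)
    global_median = np.nanmedian(log.to_numpy())
    out = {}
    for t in log.columns:
        col = log[t]
        if col.notna().sum() == 0:
            warnings.warn(f"tissue {t!r} has no detected proteins; alignment constant 0",
                          stacklevel=2)
            out[t] = col
        else:
            out[t] = col + (global_median - col.median())
    return pd.DataFrame(out, index=log.index)


# ---------------------------------------------------------------------------
# mRNA side
# ---------------------------------------------------------------------------

def mature_mrna_signal(
    exonic: CountTable, intronic: CountTable,
    exon_len: pd.Series, intron_len: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exonic density minus intronic density, in reads per kilobase.

    Transcripts with intron length 0 use the exonic term alone; negative
    differences are floored at 0.  Returns (signal, flags) where flags
    marks floored cells.
    """
    _check_labels(exonic.values.index, intronic.values.index, "transcript")
    _check_labels(exonic.values.columns, intronic.values.columns, "sample")
    _check_labels(exonic.values.index, pd.Index(exon_len.index), "exon length")
    _check_labels(exonic.values.index, pd.Index(intron_len.index), "intron length")
    exon_kb = exon_len.to_numpy(float) / 1000.0
    intron_kb = intron_len.to_numpy(float) / 1000.0
    ex = exonic.values.to_numpy(float) / exon_kb[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        inx = np.where(intron_kb[:, None] > 0,
                       intronic.values.to_numpy(float) / np.where(intron_kb > 0, intron_kb, 1.0)[:, None],
                       0.0)
    signal = ex - inx
    flags = signal < 0
    signal = np.maximum(signal, 0.0)
    idx, cols = exonic.values.index, exonic.values.columns
    return (pd.DataFrame(signal, index=idx, columns=cols),
            pd.DataFrame(flags, index=idx, columns=cols))


def size_factors(signal: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference = per-row geometric mean across samples over rows with all
    positive values; factor_s = median over rows of signal_rs / ref_r.
    """
    arr = signal.to_numpy(float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no rows with all-positive signal; cannot compute size factors")
    sub = arr[usable]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=signal.columns)


def mrna_matrix(
    signal: pd.DataFrame, factors: pd.Series, sample_sheet: SampleSheet,
    cutoff: float = READS_PER_KB_CUTOFF,
) -> pd.DataFrame:
    """Tissue-level log10 mature-mRNA matrix.

    Per sample the signal is divided by its size factor; densities below
    ``cutoff`` reads/kb are censored per sample; surviving replicate
    densities are summarised by their median per tissue and then
    log10-transformed (missing if all replicates are censored).
    """
    _check_labels(signal.columns, pd.Index(sample_sheet.frame["sample_id"]), "sample")
    norm = signal / factors.reindex(signal.columns)
    censored = norm.where(norm >= cutoff)
    out = {}
    for tissue in sample_sheet.tissues:
        samples = sample_sheet.samples_for(tissue)
        if not samples:
            raise ValueError(f"tissue {tissue!r} has no samples")
        med = censored[samples].median(axis=1)  # ignores censored replicates
        out[tissue] = np.log10(med)
    return pd.DataFrame(out, index=signal.index)


def ptr_matrix(protein: pd.DataFrame, mrna: pd.DataFrame) -> pd.DataFrame:
    """y = log10 protein - log10 mRNA on shared tissues; missing propagates."""
    shared = [t for t in protein.columns if t in mrna.columns]
    if not shared:
        raise ValueError("protein and mRNA matrices share no tissues")
    genes = protein.index.intersection(mrna.index)
    return protein.loc[genes, shared] - mrna.loc[genes, shared]


def select_major_isoform(
    ibaq_by_transcript: pd.DataFrame, transcript_to_gene: Mapping[str, str]
) -> tuple[pd.Series, list[str]]:
    """Per gene, the transcript with the largest iBAQ row sum.

    Missing intensities count as 0; ties (including all-zero genes) break
    lexicographically by transcript_id and are flagged.
    """
    sums = ibaq_by_transcript.fillna(0.0).sum(axis=1)
    genes: dict[str, tuple[float, str]] = {}
    flagged: list[str] = []
    for tid in sorted(ibaq_by_transcript.index):
        gene = transcript_to_gene[tid]
        total = float(sums[tid])
        if gene not in genes:
            genes[gene] = (total, tid)
        else:
            best_total, best_tid = genes[gene]
            if total > best_total:
                genes[gene] = (total, tid)
            elif total == best_total:
                flagged.append(gene)  # tie kept at lexicographically smaller id
    for gene, (total, _) in genes.items():
        if total == 0.0 and gene not in flagged:
            flagged.append(gene)
    return (pd.Series({g: tid for g, (_, tid) in genes.items()}).sort_index(),
            sorted(set(flagged)))


@dataclass(frozen=True)
class ExpressionResult:
    mrna: pd.DataFrame
    protein: pd.DataFrame
    ptr: pd.DataFrame
    size_factors: pd.Series
    floored: pd.DataFrame


def run_expression(
    exonic: CountTable, intronic: CountTable, ibaq: IbaqTable,
    sample_sheet: SampleSheet, exon_len: pd.Series, intron_len: pd.Series,
    cutoff: float = READS_PER_KB_CUTOFF,
) -> ExpressionResult:
    """The full preprocessing chain: counts + iBAQ -> PTR matrix."""
    signal, floored = mature_mrna_signal(exonic, intronic, exon_len, intron_len)
    factors = size_factors(signal)
    mrna = mrna_matrix(signal, factors, sample_sheet, cutoff)
    protein = summarize_protein(ibaq)
    return ExpressionResult(mrna, protein, ptr_matrix(protein, mrna), factors, floored)
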
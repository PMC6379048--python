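"""Auxiliary regressions and comparisons.

Aggregation of codon decoding times across ribosome-profiling datasets
(z-scores, per-codon medians, codon-frequency-weighted amino-acid
averages), mRNA/protein half-life effect regressions, and the Spearman
utilities used to relate PTR-AI to decoding times and half-lives.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import TranscriptRecord
from .ptr_model import RankDeficientError, _ols
from .sequence_features import SENSE_CODONS, _sense_codons

#: standard-code codon -> amino acid (sense codons only)
from Bio.Data.CodonTable import standard_dna_table as _tbl
CODON_TO_AA = {c: aa for c, aa in _tbl.forward_table.items() if c in SENSE_CODONS}


def codon_genomic_frequency(records: Sequence[TranscriptRecord]) -> pd.Series:
    """Overall sense-codon frequency across the input CDSs (weights for
    the amino-acid decoding-time average); a user-supplied 61-vector can
    be used instead."""
    counts = pd.Series(0.0, index=list(SENSE_CODONS))
    for r in records:
        for c in _sense_codons(r.cds):
            counts[c] += 1
    return counts / counts.sum()


def aggregate_decoding_times(
    tables: pd.DataFrame, codon_genomic_freq: pd.Series
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-score each dataset, take per-codon medians, and average per
    amino acid weighted by genomic codon frequency.

    ``tables``: datasets x codons decoding times (arbitrary per-dataset
    units).  Datasets with fewer than 2 codons are skipped.  Returns
    (per-dataset z-scores, per-codon median z, per-amino-acid average).
    """
    zrows = {}
    for ds, row in tables.iterrows():
        vals = row.dropna()
        if len(vals) < 2:
            warnings.warn(f"dataset {ds!r} has < 2 codons; skipped", stacklevel=2)
            continue
        zrows[ds] = (row - vals.mean()) / vals.std(ddof=0)
    if not zrows:
        raise ValueError("no usable decoding-time dataset")
    z = pd.DataFrame(zrows).T
    median_z = z.median(axis=0)
    weights = codon_genomic_freq.reindex(median_z.index)
    aa_avg = {}
    for aa in sorted(set(CODON_TO_AA.values())):
        codons = [c for c in median_z.index if CODON_TO_AA.get(c) == aa]
        w = weights[codons]
        if w.sum() <= 0:
            raise ValueError(f"amino acid {aa}: non-positive weight sum")
        aa_avg[aa] = float(np.average(median_z[codons], weights=w))
    return z, median_z, pd.Series(aa_avg)


def half_life_regression(
    half_life_log10: pd.Series, X: pd.DataFrame, min_genes: int = 200,
) -> pd.DataFrame:
    """Fold-change on half-life per frequency doubling.

    OLS of log10 half-life on codon or amino-acid log2 frequencies plus
    region length/GC covariates; effects are reported as 10^coefficient.
    """
    genes = half_life_log10.dropna().index.intersection(X.index)
    if len(genes) < min_genes:
        raise ValueError(f"need >= {min_genes} genes with half-life, got {len(genes)}")
    Xv = np.column_stack([np.ones(len(genes)), X.loc[genes].to_numpy(float)])
    fit = _ols(Xv, half_life_log10.loc[genes].to_numpy(float),
               ["(intercept)"] + list(X.columns))
    return pd.DataFrame({
        "beta": fit["beta"][1:], "se": fit["se"][1:], "p": fit["p"][1:],
        "fold_change": 10.0 ** fit["beta"][1:],
    }, index=list(X.columns))


def rank_correlate(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Spearman correlation on the inner join of two named vectors.

    Average ranks for ties; p from the t approximation.  Entries present
    in only one vector are dropped (reported via warning).
    """
    shared = a.dropna().index.intersection(b.dropna().index)
    dropped = (len(a) - len(shared)) + (len(b) - len(shared))
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared names, got {len(shared)}")
    if dropped:
        warnings.warn(f"rank_correlate: dropped {dropped} non-shared entries", stacklevel=2)
    rho, p = stats.spearmanr(a[shared], b[shared])
    return float(rho), float(p)
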
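"""De-novo k-mer motif discovery with a linear mixed model.

Each k-mer's effect on (median or tissue-centered) PTR ratios is tested
while controlling for all other k-mers through a random effect with
kinship K = Z'Z/p built from column-standardized k-mer counts, and for
region length and GC content as fixed effects:

    y = W a + x_k b_k + u + e,   u ~ N(0, s2_g K),  e ~ N(0, s2_e I)

The variance ratio lambda = s2_g/s2_e is estimated once per phenotype by
restricted maximum likelihood on the null model (no x_k) and held fixed
for all per-k-mer Wald tests (the standard mixed-model association
approximation).  The spectral decomposition of K is computed through the
k-mer Gram matrix when the number of k-mers is below the number of
genes, which makes the scan linear algebra O(n p^2) rather than O(n^3).

Significant k-mers (BH FDR across all contexts jointly) are assembled
into longer motifs by deterministic suffix-prefix overlap merging, and
candidate motifs can be scored for phylogenetic conservation against
their 10-nt flanks with a paired one-sided Wilcoxon test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ConservationTrack, TranscriptRecord, to_rna
from .ptr_model import bh_adjust
from .sequence_features import kmer_counts

Region = Literal["utr5", "cds", "utr3"]

LAMBDA_LOG_RANGE = (-10.0, 10.0)
_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class KmerDesign:
    """Standardized k-mer count design for one region and gene subset."""

    region: str
    ids: list[str]
    kmers: list[str]
    Zs: np.ndarray          # genes x kmers, column mean 0 sd 1
    W: np.ndarray           # fixed covariates: intercept, log2 length, GC
    Z_raw: pd.DataFrame     # raw counts (kept for reporting)

    @property
    def n(self) -> int:
        return self.Zs.shape[0]

    @property
    def p(self) -> int:
        return self.Zs.shape[1]

    def kinship(self) -> np.ndarray:
        """K = Zs Zs' / p; symmetric PSD, unit diagonal mean."""
        return (self.Zs @ self.Zs.T) / self.p


def region_kmer_counts(
    records: Sequence[TranscriptRecord], region: Region,
    k_min: int = 3, k_max: int = 8,
) -> pd.DataFrame:
    """Raw overlapping k-mer counts (genes x observed k-mers)."""
    rows = [kmer_counts(getattr(r, region), k_min, k_max) for r in records]
    frame = pd.DataFrame(rows, index=[r.transcript_id for r in records]).fillna(0.0)
    return frame[sorted(frame.columns, key=lambda k: (len(k), k))]


def build_kmer_design(
    records: Sequence[TranscriptRecord], region: Region,
    k_min: int = 3, k_max: int = 8,
    counts: pd.DataFrame | None = None,
) -> KmerDesign:
    """Standardize counts, drop zero-variance columns, build fixed effects."""
    if len(records) < 30:
        raise ValueError("k-mer design needs at least 30 genes")
    Z = counts if counts is not None else region_kmer_counts(records, region, k_min, k_max)
    Z = Z.loc[[r.transcript_id for r in records]]
    sd = Z.std(axis=0, ddof=0)
    keep = sd[sd > 0].index
    if len(keep) == 0:
        raise ValueError(f"all {region} k-mer columns are degenerate")
    if len(keep) < Z.shape[1]:
        warnings.warn(f"{region}: dropped {Z.shape[1] - len(keep)} zero-variance k-mers",
                      stacklevel=2)
    Zk = Z[keep]
    Zs = (Zk - Zk.mean(axis=0)) / Zk.std(axis=0, ddof=0)
    lengths = np.array([len(getattr(r, region)) for r in records], dtype=float)
    gc = np.array([
        (s.count("G") + s.count("C")) / len(s)
        for s in (getattr(r, region) for r in records)
    ])
    W = np.column_stack([np.ones(len(records)), np.log2(lengths), gc])
    return KmerDesign(region, [r.transcript_id for r in records], list(keep),
                      Zs.to_numpy(float), W, Zk)


# ---------------------------------------------------------------------------
# spectral cache and REML
# ---------------------------------------------------------------------------

@dataclass
class SpectralCache:
    """Nonzero eigenpairs of K represented without forming K when p < n."""

    d: np.ndarray        # nonzero eigenvalues of K (descending, >= 0)
    Uty: np.ndarray      # U1' y
    UtW: np.ndarray      # U1' W
    UtZ: np.ndarray      # U1' Zs
    y: np.ndarray
    W: np.ndarray
    n: int


def _spectral(design: KmerDesign, y: np.ndarray) -> SpectralCache:
    Zs, W, n, p = design.Zs, design.W, design.n, design.p
    if p < n:
        M = Zs.T @ Zs
        mu, V = np.linalg.eigh(M)
        mu = np.maximum(mu, 0.0)
        order = np.argsort(mu)[::-1]
        mu, V = mu[order], V[:, order]
        tol = mu[0] * 1e-12 if mu.size else 0.0
        keep = mu > tol
        mu, V = mu[keep], V[:, keep]
        inv_sqrt = 1.0 / np.sqrt(mu)
        # U1 = Zs V diag(1/sqrt(mu)); U1' A = diag(1/sqrt(mu)) V' Zs' A
        Uty = inv_sqrt * (V.T @ (Zs.T @ y))
        UtW = inv_sqrt[:, None] * (V.T @ (Zs.T @ W))
        UtZ = np.sqrt(mu)[:, None] * V.T          # U1' Zs exactly
        d = mu / p
    else:
        K = design.kinship()
        dd, U = np.linalg.eigh(K)
        dd = np.maximum(dd, 0.0)
        order = np.argsort(dd)[::-1]
        dd, U = dd[order], U[:, order]
        Uty, UtW, UtZ, d = U.T @ y, U.T @ W, U.T @ Zs, dd
    return SpectralCache(d, Uty, UtW, UtZ, y, W, n)


def _cross(cache: SpectralCache, lam: float):
    """Cross products A' inv(I + lam K) B for A, B in {y, W, Zs-columns}.

    inv(I + lam K) = I + U1 (1/(1+lam d) - 1) U1' on the nonzero eigenspace.
    Returns the lambda-dependent weights delta = 1/(1+lam d) - 1.
    """
    return 1.0 / (1.0 + lam * cache.d) - 1.0


def _reml_loglik(cache: SpectralCache, lam: float) -> float:
    delta = _cross(cache, lam)
    yy = cache.y @ cache.y + cache.Uty @ (delta * cache.Uty)
    Wy = cache.W.T @ cache.y + cache.UtW.T @ (delta * cache.Uty)
    WW = cache.W.T @ cache.W + cache.UtW.T @ (delta[:, None] * cache.UtW)
    sign, logdet_WW = np.linalg.slogdet(WW)
    if sign <= 0:
        return -np.inf
    ypy = yy - Wy @ np.linalg.solve(WW, Wy)
    n, q = cache.n, cache.W.shape[1]
    if ypy <= 0:
        return -np.inf
    sigma2 = ypy / (n - q)
    logdet_sigma = float(np.sum(np.log1p(lam * cache.d)))
    _, logdet_W0 = np.linalg.slogdet(cache.W.T @ cache.W)
    return -0.5 * ((n - q) * (np.log(2.0 * np.pi * sigma2) + 1.0)
                   + logdet_sigma + logdet_WW - logdet_W0)


@dataclass
class LmmFit:
    lam: float
    loglik: float
    loglik_null_variance: float   # restricted likelihood at lambda = 0
    cache: SpectralCache


def lmm_fit_null(y: np.ndarray | pd.Series, design: KmerDesign) -> LmmFit:
    """REML estimate of lambda = s2_g/s2_e for the null (no tested k-mer).

    The profiled restricted likelihood is maximised over log10(lambda) on
    a grid spanning [-10, 10], refined by golden-section search to a
    log-scale tolerance of 1e-4; the boundary lambda = 0 is always
    considered.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.n or not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be complete on the design's genes")
    cache = _spectral(design, y)
    ll0 = _reml_loglik(cache, 0.0)
    grid = np.linspace(*LAMBDA_LOG_RANGE, 101)
    lls = np.array([_reml_loglik(cache, 10.0 ** g) for g in grid])
    i = int(np.argmax(lls))
    if lls[i] <= ll0:
        return LmmFit(0.0, ll0, ll0, cache)
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    a, b = lo, hi
    c = b - _GOLD * (b - a)
    d_ = a + _GOLD * (b - a)
    fc, fd = _reml_loglik(cache, 10.0 ** c), _reml_loglik(cache, 10.0 ** d_)
    while abs(b - a) > 1e-4:
        if fc > fd:
            b, d_, fd = d_, c, fc
            c = b - _GOLD * (b - a)
            fc = _reml_loglik(cache, 10.0 ** c)
        else:
            a, c, fc = c, d_, fd
            d_ = a + _GOLD * (b - a)
            fd = _reml_loglik(cache, 10.0 ** d_)
    best = 10.0 ** ((a + b) / 2.0)
    ll = _reml_loglik(cache, best)
    if ll < ll0:
        best, ll = 0.0, ll0
    return LmmFit(float(best), float(ll), float(ll0), cache)


def lmm_association(
    y: np.ndarray | pd.Series, design: KmerDesign, fit: LmmFit | None = None,
    context: str = "median_PTR",
) -> pd.DataFrame:
    """Wald test of each k-mer with the variance structure fixed at the
    null lambda.  Computed in the eigenbasis of K, where each test is a
    weighted least squares with covariates W; collinear k-mers are
    skipped.  Returns kmer, region, context, beta, se, p.
    """
    y = np.asarray(y, dtype=float)
    if fit is None:
        fit = lmm_fit_null(y, design)
    cache = fit.cache
    delta = _cross(cache, fit.lam)
    W, Zs = cache.W, design.Zs
    # cross products through the low-rank inverse identity
    G0 = W.T @ W + cache.UtW.T @ (delta[:, None] * cache.UtW)
    b_y = W.T @ y + cache.UtW.T @ (delta * cache.Uty)
    yy = y @ y + cache.Uty @ (delta * cache.Uty)
    C = W.T @ Zs + cache.UtW.T @ (delta[:, None] * cache.UtZ)
    dvec = np.einsum("ij,ij->j", Zs, Zs) + np.einsum(
        "rj,r,rj->j", cache.UtZ, delta, cache.UtZ)
    evec = Zs.T @ y + cache.UtZ.T @ (delta * cache.Uty)

    G0_inv = np.linalg.inv(G0)
    A = G0_inv @ C                     # q x p
    s = dvec - np.einsum("qj,qj->j", C, A)
    base_rss = yy - b_y @ G0_inv @ b_y
    n, q = cache.n, W.shape[1]
    dof = n - q - 1
    tol = np.maximum(dvec, 1.0) * 1e-10
    ok = s > tol
    if not ok.all():
        warnings.warn(f"skipped {int((~ok).sum())} k-mers collinear with covariates",
                      stacklevel=2)
    beta = np.full(design.p, np.nan)
    se = np.full(design.p, np.nan)
    pval = np.full(design.p, np.nan)
    num = evec - C.T @ (G0_inv @ b_y)
    beta[ok] = num[ok] / s[ok]
    rss = base_rss - beta[ok] ** 2 * s[ok]
    sigma2 = np.maximum(rss, 0.0) / dof
    se[ok] = np.sqrt(sigma2 / s[ok])
    with np.errstate(invalid="ignore"):
        tstat = beta[ok] / se[ok]
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat), dof)
    out = pd.DataFrame({
        "kmer": [to_rna(k) for k in design.kmers],
        "region": design.region,
        "context": context,
        "beta": beta, "se": se, "p": pval,
    })
    return out.dropna(subset=["p"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# tissue scan
# ---------------------------------------------------------------------------

def tissue_scan(
    Y: pd.DataFrame, records: Sequence[TranscriptRecord],
    regions: Sequence[Region] = ("utr5", "cds", "utr3"),
    k_min: int = 3, k_max: int = 8, fdr: float = 0.1,
    include_tissue_contexts: bool = True, min_genes: int = 30,
) -> pd.DataFrame:
    """Full scan: median-PTR context plus per-tissue gene-centered
    contexts, all regions; BH adjustment across everything jointly.

    Gene-centered tissue phenotypes are y_ij minus the gene's median PTR
    across tissues.  Tissues with fewer than ``min_genes`` usable genes
    are skipped.  Adds the joint 'q' column and 'significant' at the
    requested FDR.
    """
    by_id = {r.transcript_id: r for r in records}
    results = []
    for region in regions:
        counts_all = region_kmer_counts(records, region, k_min, k_max)
        contexts: list[tuple[str, pd.Series]] = []
        median = Y.median(axis=1)
        contexts.append(("median_PTR", median.dropna()))
        if include_tissue_contexts and Y.shape[1] >= 2:
            centered = Y.sub(median, axis=0)
            for tissue in Y.columns:
                contexts.append((f"tissue:{tissue}", centered[tissue].dropna()))
        for name, y in contexts:
            genes = [g for g in y.index if g in by_id]
            if len(genes) < min_genes:
                warnings.warn(f"context {name!r}: {len(genes)} genes < {min_genes}; skipped",
                              stacklevel=2)
                continue
            design = build_kmer_design([by_id[g] for g in genes], region,
                                       k_min, k_max, counts=counts_all.loc[genes])
            fit = lmm_fit_null(y.loc[genes].to_numpy(), design)
            res = lmm_association(y.loc[genes].to_numpy(), design, fit, context=name)
            res["lambda"] = fit.lam
            results.append(res)
    if not results:
        raise ValueError("no context produced any test")
    out = pd.concat(results, ignore_index=True)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


# ---------------------------------------------------------------------------
# motif assembly
# ---------------------------------------------------------------------------

def _overlap(a: str, b: str) -> int:
    """Longest suffix of a equal to a prefix of b."""
    for k in range(min(len(a), len(b)) - 0, 0, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


def _linked(a: str, b: str) -> bool:
    if a in b or b in a:
        return True
    need = min(len(a), len(b)) - 1
    return _overlap(a, b) >= need or _overlap(b, a) >= need


def _merge_component(kmers: list[str]) -> str:
    """Greedy shortest-superstring merge: longest overlap first, ties by
    lexicographic order of the merged string."""
    pool = sorted(set(kmers))
    # containment first
    pool = [k for k in pool if not any(k != o and k in o for o in pool)]
    while len(pool) > 1:
        best = None
        for a in pool:
            for b in pool:
                if a == b:
                    continue
                ov = _overlap(a, b)
                merged = a + b[ov:]
                cand = (ov, merged, a, b)
                if best is None or cand[0] > best[0] or (
                        cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
        _, merged, a, b = best
        pool.remove(a)
        pool.remove(b)
        pool = sorted(set(pool + [merged]))
        pool = [k for k in pool if not any(k != o and k in o for o in pool)]
    return pool[0]


def assemble_motifs(significant: pd.DataFrame) -> pd.DataFrame:
    """Merge significant k-mers of each region by partial overlap.

    Two k-mers are linked iff one contains the other or they share a
    suffix-prefix overlap of at least (shorter length - 1) with matching
    letters and the same effect sign.  Each connected component merges to
    a superstring (greedy longest-overlap; ties lexicographic); the
    component representative inherits the statistics of its most
    significant member.
    """
    rows = []
    for (region, context), sub in significant.groupby(["region", "context"], sort=True):
        kmers = list(sub["kmer"])
        sign = dict(zip(sub["kmer"], np.sign(sub["beta"])))
        parent = {k: k for k in kmers}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(kmers):
            for b in kmers[i + 1:]:
                if sign[a] == sign[b] and _linked(a, b):
                    parent[find(a)] = find(b)
        comps: dict[str, list[str]] = {}
        for k in kmers:
            comps.setdefault(find(k), []).append(k)
        for members in comps.values():
            merged = _merge_component(members)
            best = sub[sub["kmer"].isin(members)].sort_values("p").iloc[0]
            rows.append({
                "motif": merged, "region": region, "context": context,
                "n_kmers": len(members), "members": ",".join(sorted(members)),
                "beta": best["beta"], "se": best["se"], "p": best["p"],
                "q": best.get("q", np.nan),
            })
    return pd.DataFrame(rows).sort_values(["region", "context", "p"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# conservation and logos
# ---------------------------------------------------------------------------

FLANK = 10


def conservation_test(
    track: ConservationTrack, records: Sequence[TranscriptRecord],
    motif: str, region: Region, min_occurrences: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Conservation of exact motif sites versus their 10-nt flanks.

    Per occurrence (with full flanks on both sides) the mean score over
    the motif positions is paired with the mean over the 20 flanking
    positions; a one-sided Wilcoxon signed-rank test asks whether motif
    sites are more conserved.  Returns (per-position mean profile, p);
    p is NaN when fewer than ``min_occurrences`` usable occurrences exist.
    """
    motif_dna = motif.upper().replace("U", "T")
    k = len(motif_dna)
    motif_means, flank_means, profiles = [], [], []
    for rec in records:
        seq = getattr(rec, region)
        scores = track.scores(rec.transcript_id, region)
        if len(scores) < len(seq):
            continue
        for i in range(len(seq) - k + 1):
            if seq[i:i + k] != motif_dna:
                continue
            if i - FLANK < 0 or i + k + FLANK > len(seq):
                continue
            window = scores[i - FLANK: i + k + FLANK]
            if np.isnan(window).any():
                continue
            motif_means.append(window[FLANK:FLANK + k].mean())
            flank_means.append(np.concatenate([window[:FLANK], window[FLANK + k:]]).mean())
            profiles.append(window)
    profile = pd.DataFrame({
        "position": np.arange(-FLANK, k + FLANK),
        "mean_score": np.mean(profiles, axis=0) if profiles else np.full(k + 2 * FLANK, np.nan),
        "n_occurrences": len(profiles),
    })
    if len(motif_means) < min_occurrences:
        warnings.warn(f"motif {motif}: only {len(motif_means)} usable occurrences",
                      stacklevel=2)
        return profile, float("nan")
    diff = np.asarray(motif_means) - np.asarray(flank_means)
    if np.allclose(diff, 0.0):
        return profile, 1.0
    res = stats.wilcoxon(motif_means, flank_means, alternative="greater")
    return profile, float(res.pvalue)


def mismatch_logo_counts(
    records: Sequence[TranscriptRecord], motif: str, region: Region,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Nucleotide counts per motif position over all windows within the
    given Hamming distance (input for information-content logos)."""
    motif_dna = motif.upper().replace("U", "T")
    k = len(motif_dna)
    if k < 3:
        raise ValueError("motif must be at least 3 nt")
    counts = np.zeros((k, 4), dtype=int)
    index = {nt: i for i, nt in enumerate("ACGT")}
    for rec in records:
        seq = getattr(rec, region)
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            mism = sum(1 for a, b in zip(window, motif_dna) if a != b)
            if mism <= max_mismatch:
                for pos, nt in enumerate(window):
                    counts[pos, index[nt]] += 1
    return pd.DataFrame(counts, columns=list("ACGU"),
                        index=pd.RangeIndex(k, name="position"))
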
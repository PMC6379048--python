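"""The interpretable multivariate PTR model and its statistics.

Tissue-wise OLS (y_ij = b_j0 + x_i' b_j + e_ij) and the shared-coefficient
variant with tissue intercepts, PTR-AI codon effects (10^coefficient =
PTR fold-change per codon-frequency doubling), amino-acid effects,
10-fold cross-validated explained variance, per-group variance
decomposition, covariate-corrected effects (Frisch-Waugh), positional
scans, Benjamini-Hochberg adjustment, LASSO candidate selection and
extended non-sequence covariates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold


class RankDeficientError(ValueError):
    """Raised when the design is rank deficient; carries aliased columns."""

    def __init__(self, aliased: list[str]):
        super().__init__(f"rank-deficient design; aliased columns: {aliased}")
        self.aliased = aliased


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if len(diag) < X.shape[1]:
        bad += [names[piv[i]] for i in range(len(diag), X.shape[1])]
    if bad:
        raise RankDeficientError(bad)


def _ols(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> dict:
    """OLS with unbiased residual variance and t-distribution p-values."""
    _check_rank(X, names)
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return {"beta": beta, "se": se, "t": t, "p": pvals, "resid": resid,
            "dof": dof, "sigma2": sigma2}


def bh_adjust(p: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values; order
    preserving and clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class FitResult:
    """Per-tissue (or shared) OLS estimates.

    ``coefficients`` etc. are features x tissues; the shared model uses a
    single column 'shared' plus per-tissue intercepts.
    """

    coefficients: pd.DataFrame
    standard_errors: pd.DataFrame
    t_statistics: pd.DataFrame
    p_values: pd.DataFrame
    q_values: pd.DataFrame
    intercepts: pd.Series
    residuals: pd.DataFrame       # genes x tissues (NaN where y missing)
    n_used: pd.Series
    skipped: tuple[str, ...] = ()


def _finish(coef, se, t, p, intercepts, resid, n_used, skipped) -> FitResult:
    pmat = pd.DataFrame(p)
    flat = pmat.to_numpy().ravel()
    mask = np.isfinite(flat)
    q = np.full(flat.shape, np.nan)
    if mask.any():
        q[mask] = bh_adjust(flat[mask])
    qmat = pd.DataFrame(q.reshape(pmat.shape), index=pmat.index, columns=pmat.columns)
    return FitResult(pd.DataFrame(coef), pd.DataFrame(se), pd.DataFrame(t), pmat, qmat,
                     pd.Series(intercepts), pd.DataFrame(resid), pd.Series(n_used),
                     tuple(skipped))


def fit_tissue_models(Y: pd.DataFrame, X: pd.DataFrame) -> FitResult:
    """Independent OLS per tissue; rows with missing y are dropped per
    tissue; a tissue with n_used <= n_features + 1 is skipped with a
    warning.  q-values are BH-adjusted across all tissues jointly.
    """
    X = X.loc[Y.index]
    feats = list(X.columns)
    coef, se, t, p, resid, inter, n_used = {}, {}, {}, {}, {}, {}, {}
    skipped = []
    for tissue in Y.columns:
        y = Y[tissue]
        rows = y.notna()
        n = int(rows.sum())
        if n <= X.shape[1] + 1:
            warnings.warn(f"tissue {tissue!r}: {n} usable genes <= {X.shape[1]} features; skipped",
                          stacklevel=2)
            skipped.append(tissue)
            continue
        Xt = np.column_stack([np.ones(n), X.loc[rows].to_numpy(float)])
        fit = _ols(Xt, y[rows].to_numpy(float), ["(intercept)"] + feats)
        coef[tissue] = pd.Series(fit["beta"][1:], index=feats)
        se[tissue] = pd.Series(fit["se"][1:], index=feats)
        t[tissue] = pd.Series(fit["t"][1:], index=feats)
        p[tissue] = pd.Series(fit["p"][1:], index=feats)
        inter[tissue] = fit["beta"][0]
        r = pd.Series(np.nan, index=Y.index)
        r[rows] = fit["resid"]
        resid[tissue] = r
        n_used[tissue] = n
    if not coef:
        raise ValueError("no tissue had enough usable genes")
    return _finish(coef, se, t, p, inter, resid, n_used, skipped)


def fit_shared_model(Y: pd.DataFrame, X: pd.DataFrame) -> FitResult:
    """Shared coefficient vector with per-tissue intercepts.

    Equivalent to OLS on the long form with tissue-indicator columns;
    observed (gene, tissue) cells only.
    """
    X = X.loc[Y.index]
    tissues = list(Y.columns)
    feats = list(X.columns)
    ys, blocks, dummies = [], [], []
    n_used = {}
    for j, tissue in enumerate(tissues):
        rows = Y[tissue].notna()
        n = int(rows.sum())
        n_used[tissue] = n
        ys.append(Y.loc[rows, tissue].to_numpy(float))
        blocks.append(X.loc[rows].to_numpy(float))
        d = np.zeros((n, len(tissues)))
        d[:, j] = 1.0
        dummies.append(d)
    y_long = np.concatenate(ys)
    X_long = np.column_stack([np.concatenate(dummies), np.concatenate(blocks)])
    names = [f"(intercept:{t})" for t in tissues] + feats
    fit = _ols(X_long, y_long, names)
    k = len(tissues)
    beta = pd.Series(fit["beta"][k:], index=feats)
    resid = pd.DataFrame(np.nan, index=Y.index, columns=tissues)
    offset = 0
    for tissue in tissues:
        rows = Y[tissue].notna()
        n = int(rows.sum())
        resid.loc[rows, tissue] = fit["resid"][offset:offset + n]
        offset += n
    return _finish(
        {"shared": beta}, {"shared": pd.Series(fit["se"][k:], index=feats)},
        {"shared": pd.Series(fit["t"][k:], index=feats)},
        {"shared": pd.Series(fit["p"][k:], index=feats)},
        pd.Series(fit["beta"][:k], index=tissues), resid, n_used, (),
    )


# ---------------------------------------------------------------------------
# codon and amino-acid effect tables
# ---------------------------------------------------------------------------

@dataclass
class CodonEffectTable:
    """Fold-change effects (10^coefficient) per codon or amino acid."""

    per_tissue: pd.DataFrame | None   # effects x tissues
    global_effects: pd.Series | None  # from the shared model


def _effect_rows(fit: FitResult, prefix: str) -> list[str]:
    rows = [c for c in fit.coefficients.index if c.startswith(prefix)]
    if not rows:
        raise ValueError(f"fit contains no {prefix!r} coefficients")
    return rows


def ptr_ai(tissue_fit: FitResult | None = None, shared_fit: FitResult | None = None) -> CodonEffectTable:
    """PTR adaptation index: 10^(codon log2-frequency coefficient).

    Tissue-specific values come from the per-tissue fits, the global value
    from the shared-coefficient fit.
    """
    per_tissue = global_effects = None
    if tissue_fit is not None:
        rows = _effect_rows(tissue_fit, "codon:")
        per_tissue = 10.0 ** tissue_fit.coefficients.loc[rows]
    if shared_fit is not None:
        rows = _effect_rows(shared_fit, "codon:")
        global_effects = 10.0 ** shared_fit.coefficients.loc[rows, "shared"]
    if per_tissue is None and global_effects is None:
        raise ValueError("provide at least one fit")
    return CodonEffectTable(per_tissue, global_effects)


def amino_acid_effects(Y: pd.DataFrame, X_aa: pd.DataFrame) -> CodonEffectTable:
    """Fold-change on PTR per amino-acid frequency doubling.

    ``X_aa`` is the design with amino-acid log2 frequencies (columns
    'aa:X') in place of codon frequencies.
    """
    tissue_fit = fit_tissue_models(Y, X_aa)
    shared_fit = fit_shared_model(Y, X_aa)
    rows = _effect_rows(shared_fit, "aa:")
    return CodonEffectTable(
        10.0 ** tissue_fit.coefficients.loc[rows],
        10.0 ** shared_fit.coefficients.loc[rows, "shared"],
    )


# ---------------------------------------------------------------------------
# cross-validated explained variance
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    r2: pd.Series          # per tissue, out-of-fold
    n_folds: int
    seed: int
    fold_assignment: pd.Series  # gene -> fold


def cv_explained_variance(
    Y: pd.DataFrame, X: pd.DataFrame, folds: int = 10, seed: int = 0
) -> CvResult:
    """Out-of-fold R^2 per tissue with gene-level fold assignment.

    A gene is held out in all tissues simultaneously (no leakage across
    tissues).  R^2 = 1 - SSE_oof / SST where SST is about the overall
    mean of the held-out (i.e. all observed) values per tissue.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    X = X.loc[Y.index]
    rng = np.random.default_rng(seed)
    genes = np.array(Y.index)
    assignment = pd.Series(np.mod(rng.permutation(len(genes)), folds), index=genes)
    pred = pd.DataFrame(np.nan, index=Y.index, columns=Y.columns)
    for f in range(folds):
        test = assignment.index[assignment == f]
        train = assignment.index[assignment != f]
        for tissue in Y.columns:
            rows = Y.loc[train, tissue].notna()
            n = int(rows.sum())
            if n <= X.shape[1] + 1:
                warnings.warn(f"fold {f}, tissue {tissue!r}: too few rows; skipped", stacklevel=2)
                continue
            Xtr = np.column_stack([np.ones(n), X.loc[train].loc[rows].to_numpy(float)])
            beta, _, _, _ = np.linalg.lstsq(Xtr, Y.loc[train].loc[rows, tissue].to_numpy(float),
                                            rcond=None)
            Xte = np.column_stack([np.ones(len(test)), X.loc[test].to_numpy(float)])
            pred.loc[test, tissue] = Xte @ beta
    r2 = {}
    for tissue in Y.columns:
        mask = Y[tissue].notna() & pred[tissue].notna()
        y = Y.loc[mask, tissue].to_numpy(float)
        yhat = pred.loc[mask, tissue].to_numpy(float)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2[tissue] = 1.0 - float(np.sum((y - yhat) ** 2)) / sst if sst > 0 else np.nan
    return CvResult(pd.Series(r2), folds, seed, assignment)


def explained_variance_by_group(
    Y: pd.DataFrame, X: pd.DataFrame, groups: pd.Series,
    folds: int = 10, seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold R^2 per feature group (single-group models) plus 'ALL'."""
    out = {}
    for group in list(dict.fromkeys(groups)) + ["ALL"]:
        cols = list(groups.index[groups == group]) if group != "ALL" else list(X.columns)
        if not cols:
            warnings.warn(f"group {group!r} empty; skipped", stacklevel=2)
            continue
        out[group] = cv_explained_variance(Y, X[cols], folds, seed).r2
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# corrected effects and positional scans
# ---------------------------------------------------------------------------

def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    beta, _, _, _ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ beta


def corrected_effect(
    y: pd.Series, X: pd.DataFrame, target_cols: Sequence[str],
) -> pd.DataFrame:
    """Effect of target columns on PTR corrected for all other features.

    Frisch-Waugh-Lovell: both y and the target columns are residualized
    on the remaining covariates (plus intercept), so the corrected effect
    equals the coefficient the targets would get in the joint OLS.
    Degrees of freedom match the joint model.
    """
    for c in target_cols:
        if c not in X.columns:
            raise ValueError(f"target column {c!r} not in design")
    cov_cols = [c for c in X.columns if c not in set(target_cols)]
    rows = y.notna()
    n = int(rows.sum())
    C = np.column_stack([np.ones(n), X.loc[rows, cov_cols].to_numpy(float)]) \
        if cov_cols else np.ones((n, 1))
    T = X.loc[rows, list(target_cols)].to_numpy(float)
    yv = y[rows].to_numpy(float)
    ry = _residualize(yv[:, None], C)[:, 0]
    RT = _residualize(T, C)
    gram = RT.T @ RT
    try:
        beta = np.linalg.solve(gram, RT.T @ ry)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientError(list(target_cols)) from exc
    resid = ry - RT @ beta
    dof = n - C.shape[1] - len(target_cols)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(gram)))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame({"beta": beta, "se": se, "t": t, "p": p}, index=list(target_cols))


def positional_scan(
    y: pd.Series, X_base: pd.DataFrame, positional: pd.DataFrame,
) -> pd.DataFrame:
    """Per-position corrected effect with BH adjustment across positions.

    Each positional column is tested one at a time against the shared
    covariate base (the base never contains the positional columns).
    """
    rows = []
    for col in positional.columns:
        design = pd.concat([X_base, positional[[col]]], axis=1)
        res = corrected_effect(y, design, [col])
        rows.append(res.loc[col])
    out = pd.DataFrame(rows, index=list(positional.columns))
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# LASSO candidate selection
# ---------------------------------------------------------------------------

def lasso_select(
    y_corrected: pd.Series, candidates: pd.DataFrame,
    folds: int = 10, seed: int = 0, one_se: bool = True,
) -> list[str]:
    """L1-penalised selection of candidate indicator columns.

    Penalty chosen by k-fold CV; with ``one_se`` the largest penalty whose
    mean CV error is within one standard error of the minimum is used.
    Constant candidate columns are dropped with a warning.  Returns the
    columns with nonzero coefficients.
    """
    rows = y_corrected.notna()
    Xc = candidates.loc[rows]
    keep = [c for c in Xc.columns if Xc[c].nunique() > 1]
    dropped = set(Xc.columns) - set(keep)
    if dropped:
        warnings.warn(f"dropping constant candidate columns: {sorted(dropped)}", stacklevel=2)
    if not keep:
        return []
    Xv = Xc[keep].to_numpy(float)
    yv = y_corrected[rows].to_numpy(float)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    lcv = LassoCV(cv=cv, alphas=60, random_state=seed, max_iter=5000).fit(Xv, yv)
    alpha = lcv.alpha_
    if one_se:
        mean_mse = lcv.mse_path_.mean(axis=1)
        se_mse = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(lcv.mse_path_.shape[1])
        imin = int(np.argmin(mean_mse))
        ok = mean_mse <= mean_mse[imin] + se_mse[imin]
        alpha = float(np.max(lcv.alphas_[ok]))
    model = Lasso(alpha=alpha, max_iter=5000).fit(Xv, yv)
    return [c for c, b in zip(keep, model.coef_) if b != 0.0]


# ---------------------------------------------------------------------------
# extended covariates
# ---------------------------------------------------------------------------

def extended_covariates(
    tables: Mapping[str, pd.DataFrame],
    kinds: Mapping[str, str],
    gene_index: pd.Index,
    pca_variance_threshold: float = 0.95,
) -> pd.DataFrame:
    """Extra design columns from non-sequence covariate tables.

    kinds per table: 'binary' passes indicators through; 'count' applies
    log2(count + 1); 'pca_block' replaces a high-dimensional block by the
    smallest number of leading principal components reaching the
    cumulative explained-variance threshold.  Tables are inner-joined to
    the gene universe with a report for mismatches.
    """
    blocks = []
    for name, table in tables.items():
        kind = kinds[name]
        missing = gene_index.difference(table.index)
        if len(missing):
            warnings.warn(f"table {name!r}: {len(missing)} genes absent; inner join", stacklevel=2)
        sub = table.reindex(gene_index).dropna()
        if kind == "binary":
            block = sub.add_prefix(f"{name}:")
        elif kind == "count":
            block = np.log2(sub + 1.0).add_prefix(f"{name}:")
        elif kind == "pca_block":
            X = sub.to_numpy(float)
            X = X - X.mean(axis=0)
            pca = PCA(n_components=min(X.shape) - 1 or 1, random_state=0).fit(X)
            cum = np.cumsum(pca.explained_variance_ratio_)
            k = int(np.searchsorted(cum, pca_variance_threshold) + 1)
            k = min(k, len(cum))
            scores = pca.transform(X)[:, :k]
            block = pd.DataFrame(scores, index=sub.index,
                                 columns=[f"{name}:pc{i+1}" for i in range(k)])
        else:
            raise ValueError(f"unknown covariate kind {kind!r} for table {name!r}")
        blocks.append(block)
    out = pd.concat(blocks, axis=1, join="inner")
    return out
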
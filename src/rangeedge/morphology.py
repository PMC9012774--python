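"""Morphometric pipeline: allometric size-correction, sex test, PCA, LDA.

Works on a per-specimen table with snout–vent length (SVL), continuous
morphometric traits (tail, head and limb measurements in mm), integer
meristic counts (femoral pores, lamellae, scale rows) plus sex and
subpopulation labels. Morphometrics are ln-transformed and size-corrected
by regressing each ln trait on ln SVL over all specimens pooled and
keeping the residuals; meristics are z-score normalised but not
size-corrected. Downstream: a Mann–Whitney U sex-difference screen, PCA
of the combined standardised matrix, and a linear discriminant classifier
with confusion matrix and per-group assignment accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simgen import MERISTIC_TRAITS, MORPHOMETRIC_TRAITS


def _trait_columns(M: pd.DataFrame):
    morpho = [t for t in MORPHOMETRIC_TRAITS if t in M.columns]
    meristic = [t for t in MERISTIC_TRAITS if t in M.columns]
    return morpho, meristic


def size_correct(M: pd.DataFrame, on_log_svl: bool = True) -> pd.DataFrame:
    """Remove allometric size dependence from the morphometric traits.

    Each morphometric trait is ln-transformed and regressed on ln SVL
    (or raw SVL with ``on_log_svl=False``) by ordinary least squares over
    all specimens pooled; the returned table holds the residuals plus
    z-scored meristic counts, with sex and population carried through.
    Rows with any missing trait are dropped (listwise deletion), with
    the count recorded in ``DataFrame.attrs["n_dropped"]``.
    """
    morpho, meristic = _trait_columns(M)
    cols = ["SVL", *morpho, *meristic]
    complete = M.dropna(subset=[c for c in cols if c in M.columns])
    n_dropped = len(M) - len(complete)
    if len(complete) < 3:
        raise ValueError("need at least 3 complete specimens")
    svl = complete["SVL"].to_numpy(dtype=float)
    if np.any(svl <= 0):
        raise ValueError("SVL must be positive")
    x = np.log(svl) if on_log_svl else svl
    if np.ptp(x) == 0:
        raise ValueError("zero variance in SVL; cannot size-correct")
    X = np.column_stack([np.ones_like(x), x])
    out = pd.DataFrame(index=complete.index)
    for trait in morpho:
        y = np.log(complete[trait].to_numpy(dtype=float))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[trait] = y - X @ beta
    for trait in meristic:
        v = complete[trait].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        out[trait] = (v - v.mean()) / sd if sd > 0 else 0.0
    for label in ("sex", "population"):
        if label in complete.columns:
            out[label] = complete[label].to_numpy()
    out.attrs["n_dropped"] = n_dropped
    out.attrs["residual_traits"] = morpho
    out.attrs["meristic_traits"] = meristic
    return out


def sex_difference_test(resid: pd.DataFrame) -> pd.DataFrame:
    """Mann–Whitney U screen for sexual dimorphism.

    Applied per residual/normalised trait and, as an overall summary, to
    the first principal component of the combined matrix. Two-sided
    p-values; no pooling decision is made here — the report is the
    deliverable.
    """
    if "sex" not in resid.columns:
        raise ValueError("table has no 'sex' column")
    sexes = resid["sex"].unique()
    if len(sexes) != 2:
        raise ValueError("exactly two sexes required")
    ga = resid[resid["sex"] == sexes[0]]
    gb = resid[resid["sex"] == sexes[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each sex needs at least 2 specimens")
    traits = resid.attrs.get("residual_traits", []) + resid.attrs.get(
        "meristic_traits", []
    )
    traits = [t for t in traits if t in resid.columns]
    rows = []
    for trait in traits:
        u, p = stats.mannwhitneyu(ga[trait], gb[trait], alternative="two-sided")
        rows.append({"variable": trait, "U": float(u), "p_value": float(p)})
    pca = morph_pca(resid)
    pc1 = pd.Series(pca.scores[:, 0], index=resid.index)
    u, p = stats.mannwhitneyu(pc1[ga.index], pc1[gb.index], alternative="two-sided")
    rows.append({"variable": "PC1", "U": float(u), "p_value": float(p)})
    return pd.DataFrame(rows)


@dataclass
class MorphPCAResult:
    scores: np.ndarray
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray


def morph_pca(resid: pd.DataFrame) -> MorphPCAResult:
    """PCA of the standardised residual + meristic matrix.

    Columns are z-scored before decomposition so measurement and count
    traits contribute comparably; component signs follow the
    largest-magnitude-loading-positive convention.
    """
    traits = resid.attrs.get("residual_traits", []) + resid.attrs.get(
        "meristic_traits", []
    )
    traits = [t for t in traits if t in resid.columns] or [
        c for c in resid.columns if c not in ("sex", "population")
    ]
    X = resid[traits].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 specimens for PCA")
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    X = X / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    loadings = Vt.T
    for c in range(loadings.shape[1]):
        top = np.argmax(np.abs(loadings[:, c]))
        if loadings[top, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    frac = S**2 / (S**2).sum() if (S**2).sum() > 0 else np.zeros_like(S)
    return MorphPCAResult(
        scores,
        pd.DataFrame(loadings, index=traits, columns=[f"PC{i+1}" for i in range(loadings.shape[1])]),
        frac,
    )


@dataclass
class MorphLDAResult:
    confusion: pd.DataFrame
    per_group_accuracy: pd.Series
    overall_accuracy: float
    cv: str
    excluded_groups: list


def morph_lda(
    resid: pd.DataFrame, groups=None, cv: str = "leave-one-out"
) -> MorphLDAResult:
    """Linear discriminant classification of specimens into groups.

    ``cv`` is ``"leave-one-out"`` (default; each specimen predicted by a
    model trained without it) or ``"resubstitution"`` (train = test,
    optimistic). Groups with fewer than 2 specimens are excluded with a
    record in the result. Reports the confusion matrix (rows = true
    group), per-group accuracy (diagonal / row sum) and overall accuracy
    (trace / total).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    if cv not in ("leave-one-out", "resubstitution"):
        raise ValueError("cv must be 'leave-one-out' or 'resubstitution'")
    labels = np.asarray(
        groups if groups is not None else resid["population"], dtype=object
    )
    traits = resid.attrs.get("residual_traits", []) + resid.attrs.get(
        "meristic_traits", []
    )
    traits = [t for t in traits if t in resid.columns] or [
        c for c in resid.columns if c not in ("sex", "population")
    ]
    X = resid[traits].to_numpy(dtype=float)
    uniq, counts = np.unique(labels, return_counts=True)
    excluded = [str(u) for u, c in zip(uniq, counts) if c < 2]
    keep = ~np.isin(labels, excluded)
    X, labels = X[keep], labels[keep]
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups with >= 2 specimens")

    def fit_predict(train_idx, test_idx):
        lda = LinearDiscriminantAnalysis()
        try:
            lda.fit(X[train_idx], labels[train_idx])
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular pooled covariance; reduce dimensions (e.g. PCA first)"
            ) from exc
        return lda.predict(X[test_idx])

    n = len(labels)
    if cv == "resubstitution":
        pred = fit_predict(np.arange(n), np.arange(n))
    else:
        pred = np.empty(n, dtype=object)
        for i in range(n):
            train = np.setdiff1d(np.arange(n), [i])
            if len(np.unique(labels[train])) < len(uniq):
                # removing the specimen emptied its group: predict with all data
                train = np.arange(n)
            pred[i] = fit_predict(train, np.array([i]))[0]
    confusion = pd.crosstab(
        pd.Series(labels, name="true"), pd.Series(pred, name="assigned")
    ).reindex(index=uniq, columns=uniq, fill_value=0)
    row_sums = confusion.sum(axis=1)
    per_group = pd.Series(np.diag(confusion) / row_sums, index=confusion.index)
    overall = float(np.trace(confusion) / confusion.to_numpy().sum())
    return MorphLDAResult(confusion, per_group, overall, cv, excluded)
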
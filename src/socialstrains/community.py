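"""Compositional diversity: CLR, alpha metrics, Aitchison distance, PCoA, PERMANOVA.

Relative-abundance tables (samples x species, proportions) are filtered at a
minimum mean abundance, zero-imputed with each species' minimum nonzero
proportion, re-closed, and centered-log-ratio transformed. Beta diversity is
the Aitchison distance (Euclidean on CLR rows) ordinated by classical PCoA;
group effects on the distance matrix are tested with a permutational ANOVA
(pseudo-F on the Gower-centered decomposition, label permutations).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "read_abundance",
    "filter_species",
    "CLRTransformer",
    "clr_transform",
    "alpha_metrics",
    "aitchison_distance",
    "pcoa",
    "permanova",
    "prevalence_core_summary",
]


def read_abundance(path: Path | str) -> pd.DataFrame:
    """Read a MetaPhlAn-style merged table into a samples x species proportion table.

    Keeps rows whose clade name ends at the species level (contains an
    ``s__`` label and no strain-level ``t__`` refinement); percent-scale
    tables (columns summing to ~100) are rescaled to proportions.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    is_species = [("s__" in c) and ("t__" not in c) for c in raw.index]
    sp = raw.loc[is_species]
    sp.index = [c[c.index("s__") :] for c in sp.index]
    table = sp.T
    colsum = table.sum(axis=1)
    if colsum.max() > 1.5:  # percent scale
        table = table / 100.0
    return table


def filter_species(table: pd.DataFrame, min_mean: float = 0.001) -> pd.DataFrame:
    """Keep species whose mean relative abundance across samples is >= min_mean."""
    return table.loc[:, table.mean(axis=0) >= min_mean]


class CLRTransformer(TransformerMixin, BaseEstimator):
    """Centered log-ratio transform with minimum-proportion zero imputation.

    scikit-learn style transformer: ``fit`` learns each species' minimum
    nonzero proportion from the training table; ``transform`` imputes zeros
    with those minima, re-closes each row to unit sum, and applies
    ``x -> ln(x / geometric_mean(row))`` so every output row sums to 0.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = self._validate(X)
        arr = X.to_numpy(dtype=float)
        if (arr > 0).sum(axis=0).min() == 0:
            empty = X.columns[(arr > 0).sum(axis=0) == 0]
            raise ValueError(f"species with no nonzero abundance: {list(empty)[:5]}")
        mins = np.where(arr > 0, arr, np.inf).min(axis=0)
        self.impute_values_ = pd.Series(mins, index=X.columns)
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._validate(X)
        arr = X.to_numpy(dtype=float)
        imput = self.impute_values_.reindex(X.columns).to_numpy()
        arr = np.where(arr > 0, arr, imput[None, :])
        arr = arr / arr.sum(axis=1, keepdims=True)
        log = np.log(arr)
        clr = log - log.mean(axis=1, keepdims=True)
        return pd.DataFrame(clr, index=X.index, columns=X.columns)

    @staticmethod
    def _validate(X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if (X.to_numpy(dtype=float) < 0).any():
            raise ValueError("abundances must be non-negative")
        return X


def clr_transform(table: pd.DataFrame) -> pd.DataFrame:
    """One-shot CLR of a proportion table (fit and transform on the same data)."""
    return CLRTransformer().fit_transform(table)


def alpha_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Observed richness, Shannon, Simpson variants and Pielou evenness.

    Shannon uses the natural log. Simpson is reported as 1 - sum(p^2)
    (columns for the raw sum D and inverse 1/D are included). Pielou =
    Shannon / ln(Observed), undefined (NaN) for single-species samples.
    """
    arr = table.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample")
    p = arr / arr.sum(axis=1, keepdims=True)
    observed = (arr > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        shannon = -plogp.sum(axis=1)
        d = (p**2).sum(axis=1)
        pielou = np.where(observed > 1, shannon / np.log(observed), np.nan)
    return pd.DataFrame(
        {
            "observed": observed,
            "shannon": shannon,
            "simpson": 1.0 - d,
            "simpson_d": d,
            "inverse_simpson": 1.0 / d,
            "pielou": pielou,
        },
        index=table.index,
    )


def aitchison_distance(clr: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between CLR rows (the Aitchison distance)."""
    mat = squareform(pdist(clr.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(mat, index=clr.index, columns=clr.index)


def pcoa(dist: pd.DataFrame, n_axes: int | None = None) -> dict:
    """Classical principal coordinate analysis (Torgerson scaling).

    Double-centers the squared distance matrix and eigendecomposes it;
    coordinates are returned for positive-eigenvalue axes ordered by
    decreasing eigenvalue. For a Euclidean input (e.g. Aitchison distance)
    negative eigenvalues are numerically ~0.
    """
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-10
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    rel = vals[pos] / vals[pos].sum() if pos.any() else vals[:0]
    return {
        "coordinates": pd.DataFrame(coords, index=dist.index, columns=cols),
        "eigenvalues": vals,
        "proportion_explained": rel[: coords.shape[1]],
    }


def permanova(
    dist: pd.DataFrame, labels, n_perm: int = 999, seed: int = 0
) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    Decomposes the Gower-centered matrix into between- and within-group sums
    of squares: R2 = SS_between / SS_total, pseudo-F = (SS_b / (k - 1)) /
    (SS_w / (n - k)), and the p-value is ``(1 + #{F_perm >= F_obs}) /
    (n_perm + 1)`` over seeded label permutations. The Ezekiel-adjusted R2 is
    reported alongside.
    """
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels must cover all samples")
    uniq, idx = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    d2 = d**2
    sst = d2[np.triu_indices(n, k=1)].sum() / n

    def ss_within(assign: np.ndarray) -> float:
        ssw = 0.0
        for g in range(k):
            members = np.flatnonzero(assign == g)
            if len(members) > 1:
                sub = d2[np.ix_(members, members)]
                ssw += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
        return ssw

    def f_stat(assign: np.ndarray) -> tuple[float, float]:
        ssw = ss_within(assign)
        ssb = sst - ssw
        return (ssb / (k - 1)) / (ssw / (n - k)) if ssw > 0 else np.inf, ssb / sst

    f_obs, r2 = f_stat(idx)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_p, _ = f_stat(rng.permutation(idx))
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else np.nan
    return {
        "R2": float(r2),
        "adjusted_R2": float(adj_r2),
        "pseudo_F": float(f_obs),
        "p": float(p),
        "n_permutations": n_perm,
        "seed": seed,
        "n_samples": n,
        "n_groups": k,
    }


def prevalence_core_summary(table: pd.DataFrame, core_fraction: float = 0.66) -> dict:
    """Per-species prevalence and core-microbiome class counts.

    Classes: present in all samples, in all but one, in at least
    ``core_fraction`` of samples, and the rest. Presence = abundance > 0.
    """
    n = table.shape[0]
    species = table.columns
    if n == 0 or len(species) == 0:
        empty = pd.Series(dtype=float)
        return {"prevalence": empty, "classes": {"all": 0, "all_but_one": 0, "ge_core": 0, "other": 0}, "fractions": {}}
    count = (table.to_numpy(dtype=float) > 0).sum(axis=0)
    prevalence = pd.Series(count / n, index=species, name="prevalence")
    in_all = int((count == n).sum())
    all_but_one = int((count == n - 1).sum())
    ge_core = int(((count / n >= core_fraction) & (count < n - 1)).sum())
    other = len(species) - in_all - all_but_one - ge_core
    classes = {"all": in_all, "all_but_one": all_but_one, "ge_core": ge_core, "other": other}
    fractions = {key: val / len(species) for key, val in classes.items()}
    return {"prevalence": prevalence, "classes": classes, "fractions": fractions}
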
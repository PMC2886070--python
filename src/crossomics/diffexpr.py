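"""Differential-expression calling for transcripts and proteins.

Transcripts: an ordinary least-squares linear model is fitted to the log2
values of each gene separately (cell-means design over species), and each
contrast is tested with a two-sided t-test on the contrast estimate.

Proteins: species-vs-rest contrasts use two-sided Wilcoxon rank-sum tests
on per-replicate NSAF values (spectral-count-derived abundances are not
normal enough for t-tests in the 3-vs-6 setting); pairwise species
contrasts use two-sample t-tests on pseudo-counted NSAF values, which are
approximately normal. All p-values are Benjamini-Hochberg adjusted across
loci within each contrast.

Note on power: with 3 replicates against 6, the smallest attainable exact
two-sided Wilcoxon p-value is 2/84 ~ 0.024, and after BH adjustment across
many loci no rank test can clear 0.05. At paper-like replicate numbers the
group tests therefore order loci rather than certify them; the pairwise
t-tests carry the significance calls.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError

__all__ = [
    "ContrastSpec",
    "study_contrasts",
    "build_design",
    "contrast_vector",
    "fit_transcript_contrasts",
    "protein_group_test",
    "protein_pairwise_test",
    "adjust_bh",
    "call_regulated",
]

COLUMNS = ["locus", "contrast", "log2fc", "stat", "p_raw", "p_adj", "call"]


@dataclass(frozen=True)
class ContrastSpec:
    """One species comparison: the target against one species or the rest."""

    name: str
    kind: str  # "group" (one vs rest) or "pairwise"
    target: str
    others: tuple

    def __post_init__(self):
        if self.kind not in ("group", "pairwise"):
            raise ConfigError(f"unknown contrast kind: {self.kind}")
        if self.kind == "pairwise" and len(self.others) != 1:
            raise ConfigError("pairwise contrast needs exactly one comparison species")


def study_contrasts(species=("CH", "EX", "NZ")) -> list[ContrastSpec]:
    """The six study contrasts: each species vs the rest, plus all pairs."""
    species = list(species)
    specs = [
        ContrastSpec(f"{s}_vs_{'+'.join(o for o in species if o != s)}", "group", s,
                     tuple(o for o in species if o != s))
        for s in species
    ]
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            specs.append(ContrastSpec(f"{a}_vs_{b}", "pairwise", a, (b,)))
    return specs


def build_design(species_of_sample: pd.Series) -> pd.DataFrame:
    """Cell-means design: one indicator column per species, rows = samples."""
    return pd.get_dummies(species_of_sample).astype(float)


def contrast_vector(spec: ContrastSpec, columns) -> np.ndarray:
    """Coefficient vector: target minus the (average of the) others."""
    c = np.zeros(len(columns))
    cols = list(columns)
    c[cols.index(spec.target)] = 1.0
    for o in spec.others:
        c[cols.index(o)] = -1.0 / len(spec.others)
    return c


def _name_confounded(X: pd.DataFrame) -> list:
    """Columns that do not increase the design rank when added left to right."""
    bad, kept = [], np.empty((len(X), 0))
    for col in X.columns:
        cand = np.column_stack([kept, X[col].to_numpy()])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(kept):
            kept = cand
        else:
            bad.append(col)
    return bad


def fit_transcript_contrasts(
    log_matrix: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: list[ContrastSpec],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene OLS on log2 values with t-tests on the given contrasts.

    Parameters
    ----------
    log_matrix : DataFrame
        Genes (rows) x arrays (columns), log2 scale.
    design : DataFrame
        Arrays (rows, same order as ``log_matrix`` columns) x coefficients.

    Returns
    -------
    DataFrame
        Tidy table with one row per gene per contrast
        (columns ``locus, contrast, log2fc, stat, p_raw, p_adj, call``).
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if log_matrix.shape[1] != n:
        raise ConfigError("design rows must match the array columns of the matrix")
    if np.linalg.matrix_rank(X) < p:
        raise ConfigError(f"rank-deficient design; confounded columns: {_name_confounded(design)}")

    Y = log_matrix.to_numpy(dtype=float)  # genes x arrays
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv  # genes x p
    resid = Y - beta @ X.T
    df = n - p
    if df <= 0:
        warnings.warn("saturated design: no residual degrees of freedom; p-values undefined")
        sigma2 = np.full(Y.shape[0], np.nan)
    else:
        sigma2 = (resid**2).sum(axis=1) / df

    frames = []
    for spec in contrasts:
        c = contrast_vector(spec, design.columns)
        est = beta @ c
        var = sigma2 * float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / np.sqrt(var)
        p_raw = 2 * stats.t.sf(np.abs(t), df) if df > 0 else np.full_like(est, np.nan)
        p_raw = np.where(np.isnan(p_raw) & (est == 0), 1.0, p_raw)
        frames.append(_assemble(log_matrix.index, spec.name, est, t, p_raw, alpha))
    return pd.concat(frames, ignore_index=True)


def _assemble(loci, contrast, log2fc, stat, p_raw, alpha) -> pd.DataFrame:
    p_raw = np.asarray(p_raw, dtype=float)
    valid = ~np.isnan(p_raw)
    p_adj = np.full_like(p_raw, np.nan)
    if valid.any():
        p_adj[valid] = adjust_bh(p_raw[valid])
    call = np.where(
        (p_adj < alpha) & (log2fc > 0), "up",
        np.where((p_adj < alpha) & (log2fc < 0), "down", "ns"),
    )
    call = np.where(np.isnan(p_adj), "ns", call)
    return pd.DataFrame(
        {"locus": loci, "contrast": contrast, "log2fc": log2fc, "stat": stat,
         "p_raw": p_raw, "p_adj": p_adj, "call": call}
    )


def _log2_ratio_of_means(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    mx, my = x.mean(axis=1), y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(mx) - np.log2(my)


def protein_group_test(
    nsaf: pd.DataFrame,
    species: pd.Series,
    target: str,
    others=None,
    alpha: float = 0.05,
    nsaf_fc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum test of one species' NSAF values against the rest.

    Exact p-values when both sides have <= 8 replicates and no ties occur;
    otherwise the normal approximation with continuity and tie correction.
    ``nsaf_fc`` (typically the pseudo-counted table) supplies the values
    used for the log2 fold change of means; it defaults to ``nsaf``.

    Returns tidy rows for the contrast ``{target}_vs_{others joined by +}``.
    """
    labels = [s for s in dict.fromkeys(species)]
    if target not in labels:
        raise DataError(f"unknown species label: {target!r}")
    if others is None:
        others = [s for s in labels if s != target]
    others = list(others)
    reps_t = [c for c in nsaf.columns if species[c] == target]
    reps_o = [c for c in nsaf.columns if species[c] in others]
    if len(reps_t) < 2 or len(reps_o) < 2:
        raise DataError("need at least two replicates on each side")

    x = nsaf[reps_t].to_numpy(dtype=float)
    y = nsaf[reps_o].to_numpy(dtype=float)
    p_raw = np.ones(len(nsaf))
    stat = np.zeros(len(nsaf))
    for i in range(len(nsaf)):
        if np.ptp(np.concatenate([x[i], y[i]])) == 0:
            stat[i] = len(reps_t) * len(reps_o) / 2.0
            continue  # all values identical -> p = 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(x[i], y[i], alternative="two-sided", method="auto")
        stat[i], p_raw[i] = res.statistic, min(float(res.pvalue), 1.0)

    fc_src = nsaf if nsaf_fc is None else nsaf_fc
    log2fc = _log2_ratio_of_means(
        fc_src[reps_t].to_numpy(dtype=float), fc_src[reps_o].to_numpy(dtype=float)
    )
    name = f"{target}_vs_{'+'.join(others)}"
    return _assemble(nsaf.index, name, log2fc, stat, p_raw, alpha)


def protein_pairwise_test(
    nsaf_with_fraction: pd.DataFrame,
    species: pd.Series,
    a: str,
    b: str,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sample t-test per locus on pseudo-counted NSAF values.

    Welch's test by default (robust to unequal variances at n=3); set
    ``equal_var=True`` for the pooled-variance textbook variant.
    Degenerate loci (zero variance on both sides) get p=1 when the means
    agree and p=0 (infinite statistic) when they differ.
    """
    reps_a = [c for c in nsaf_with_fraction.columns if species[c] == a]
    reps_b = [c for c in nsaf_with_fraction.columns if species[c] == b]
    if len(reps_a) < 2 or len(reps_b) < 2:
        raise DataError("need at least two replicates per species")
    x = nsaf_with_fraction[reps_a].to_numpy(dtype=float)
    y = nsaf_with_fraction[reps_b].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)

    zero_var = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    same = zero_var & (x.mean(axis=1) == y.mean(axis=1))
    diff = zero_var & ~same
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(diff, np.sign(x.mean(axis=1) - y.mean(axis=1)) * np.inf, t)
    p = np.where(diff, 0.0, p)

    log2fc = _log2_ratio_of_means(x, y)
    return _assemble(nsaf_with_fraction.index, f"{a}_vs_{b}", log2fc, t, p, alpha)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consensus_calls(call_sets: list[dict]) -> dict:
    """Intersect regulated-locus calls across several analysis settings.

    ``call_sets`` holds outputs of :func:`call_regulated` from runs with
    different alpha/filter choices; a locus is kept only when every run
    calls it, in the same direction — a conservative intersection mode for
    analyses whose pre-processing is uncertain.
    """
    if not call_sets:
        return {}
    contrasts = set(call_sets[0])
    for cs in call_sets[1:]:
        contrasts &= set(cs)
    out = {}
    for contrast in contrasts:
        ref = call_sets[0][contrast]
        out[contrast] = {
            direction: [
                locus
                for locus in ref[direction]
                if all(locus in cs[contrast][direction] for cs in call_sets[1:])
            ]
            for direction in ("up", "down")
        }
    return out


def call_regulated(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Up/down locus lists per contrast from a tidy DE table.

    up = {log2fc > 0 and p_adj < alpha}; down symmetric; disjoint by
    construction.
    """
    out: dict = {}
    for contrast, sub in table.groupby("contrast", sort=False):
        sig = sub["p_adj"] < alpha
        out[contrast] = {
            "up": sub.loc[sig & (sub["log2fc"] > 0), "locus"].tolist(),
            "down": sub.loc[sig & (sub["log2fc"] < 0), "locus"].tolist(),
        }
    return out
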
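"""Cross-layer concordance: common locus set, Spearman correlations, and
size-corrected overlap of regulated-gene lists with a permutation null.

Transcript and protein surveys capture different gene universes, so raw
overlap counts are misleading. All overlap statistics are therefore
computed after restricting both regulated lists to the loci measured by
*both* layers ("size correction"). Two complementary percentages are
reported: the proportion of regulated transcripts confirmed by proteins
(100*k/a) and the proportion of regulated proteins confirmed by
transcripts (100*k/b). Significance of an observed overlap k is judged
against the distribution of overlaps of two uniformly random subsets of
the same sizes drawn from the common universe.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "CommonSet",
    "CorrelationMatrix",
    "OverlapResult",
    "common_gene_set",
    "correlation_matrix",
    "overlap_analysis",
    "permutation_overlap_pvalue",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding (0.5 always rounds away from zero)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class CommonSet:
    """Loci measured by both the transcript and the protein survey."""

    loci: list
    n_transcript: int
    n_protein: int

    def __len__(self):
        return len(self.loci)


def common_gene_set(transcript_ids, protein_ids) -> CommonSet:
    """Order-stable intersection of the two locus universes.

    Follows the order of ``transcript_ids``; an empty intersection is a
    warning, not an error.
    """
    t_ids = list(dict.fromkeys(transcript_ids))
    p_set = set(protein_ids)
    loci = [g for g in t_ids if g in p_set]
    if not loci:
        warnings.warn("transcript and protein universes share no loci")
    return CommonSet(loci, n_transcript=len(t_ids), n_protein=len(set(protein_ids)))


@dataclass
class CorrelationMatrix:
    """Spearman rank correlations among transcript and protein columns."""

    rho: pd.DataFrame  # labels x labels, symmetric, diagonal 1
    n_loci: int

    def to_frame(self) -> pd.DataFrame:
        return self.rho


def correlation_matrix(
    transcript_log2: pd.DataFrame,
    protein_log2: pd.DataFrame,
    common: CommonSet,
    transcript_suffix: str = "_T",
    protein_suffix: str = "_P",
) -> CorrelationMatrix:
    """All pairwise Spearman correlations among per-species abundance columns.

    Both matrices are loci x species; only the common loci enter. Ties are
    midranked (scipy default). A constant column has no defined rank
    correlation: its entries are reported as NaN with a warning.
    """
    t = transcript_log2.loc[common.loci]
    p = protein_log2.loc[common.loci]
    combined = pd.concat(
        [t.add_suffix(transcript_suffix), p.add_suffix(protein_suffix)], axis=1
    )
    X = combined.to_numpy(dtype=float)
    constant = [c for i, c in enumerate(combined.columns) if np.ptp(X[:, i]) == 0]
    if constant:
        warnings.warn(f"constant columns, correlation undefined: {constant}")
    rho = stats.spearmanr(X, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the two-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(rho, index=combined.columns, columns=combined.columns)
    for c in constant:
        out.loc[c, :] = np.nan
        out.loc[:, c] = np.nan
        out.loc[c, c] = 1.0
    np.fill_diagonal(out.values, 1.0)
    return CorrelationMatrix(out, n_loci=len(common))


@dataclass
class OverlapResult:
    """Size-corrected overlap of two regulated-gene lists."""

    contrast: str
    a: int  # regulated transcripts within the common set
    b: int  # regulated proteins within the common set
    k: int  # regulated in both
    upper_pct: float | None  # 100*k/a: transcripts confirmed by proteins
    lower_pct: float | None  # 100*k/b: proteins confirmed by transcripts
    p_perm: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    @property
    def upper_pct_display(self):
        return None if self.upper_pct is None else round_half_up(self.upper_pct)

    @property
    def lower_pct_display(self):
        return None if self.lower_pct is None else round_half_up(self.lower_pct)


def overlap_analysis(t_up, p_up, common: CommonSet, contrast: str = "") -> OverlapResult:
    """Intersect two regulated lists after restriction to the common set.

    Lists may extend beyond the common universe; the size correction
    restricts them first. When a side is empty its percentage is
    undefined (None).
    """
    universe = set(common.loci)
    t_set = set(t_up) & universe
    p_set = set(p_up) & universe
    a, b, k = len(t_set), len(p_set), len(t_set & p_set)
    upper = 100.0 * k / a if a else None
    lower = 100.0 * k / b if b else None
    if a == 0 or b == 0:
        warnings.warn(f"empty regulated list in overlap for {contrast or 'contrast'}")
    return OverlapResult(contrast, a, b, k, upper, lower)


def permutation_overlap_pvalue(
    a: int,
    b: int,
    k_obs: int,
    universe_n: int,
    n_perm: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """One-sided permutation p-value for an overlap of k_obs loci.

    Draws two independent uniform subsets (sizes a and b, without
    replacement) from a universe of ``universe_n`` loci ``n_perm`` times
    and reports ``p = (1 + #{overlap >= k_obs}) / (1 + n_perm)``. The +1
    keeps p strictly positive. For uniform subsets the overlap is
    hypergeometric, which serves as a closed-form cross-check in tests.
    """
    if a > universe_n or b > universe_n:
        raise DataError("set sizes exceed the universe")
    if k_obs > min(a, b) or k_obs < 0:
        raise DataError(f"impossible observed overlap k={k_obs} for sizes ({a}, {b})")
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = np.zeros(universe_n, dtype=bool)
    hits = 0
    for _ in range(n_perm):
        set_a = rng.choice(universe_n, size=a, replace=False)
        set_b = rng.choice(universe_n, size=b, replace=False)
        mask[:] = False
        mask[set_a] = True
        if int(mask[set_b].sum()) >= k_obs:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def hypergeom_overlap_tail(a: int, b: int, k_obs: int, universe_n: int) -> float:
    """Closed-form P(overlap >= k_obs) for uniform random subsets."""
    return float(stats.hypergeom.sf(k_obs - 1, universe_n, a, b))
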
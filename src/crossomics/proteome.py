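"""Spectral-count filtering and NSAF quantitation.

The normalized spectral abundance factor (NSAF) of protein *k* in sample
*i* is

    NSAF_k = (SpC_k / MW_k) / sum_j (SpC_j / MW_j)

where SpC is the number of MS/MS spectra matched to the protein and MW its
molecular weight in kDa. Dividing by MW corrects for the fact that longer
proteins yield more tryptic peptides; the final division makes the values
sum to one per sample so they are comparable across runs of different
depth. A per-species "summed" variant (NSAF_S) first pools the spectral
counts of all replicates of a species and then normalizes.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "SpectralCountTable",
    "combine_isoforms",
    "filter_proteins",
    "compute_nsaf",
    "nsaf_table",
    "compute_nsaf_summed",
    "add_spectral_fraction",
]

_ISOFORM_RE = re.compile(r"^(.*?)(\.\d+)?$")


@dataclass
class SpectralCountTable:
    """Spectral counts per protein per replicate, with protein metadata.

    Parameters
    ----------
    counts : DataFrame
        Proteins (rows) x replicates (columns), non-negative. Integer in raw
        data; fractional after :func:`add_spectral_fraction`.
    mw_kda : Series
        Molecular weight in kDa per protein, index-aligned with ``counts``.
    n_peptides : Series
        Number of distinct peptides supporting each protein.
    species : Series
        Maps each replicate (column of ``counts``) to a species label.
    """

    counts: pd.DataFrame
    mw_kda: pd.Series
    n_peptides: pd.Series
    species: pd.Series

    def __post_init__(self):
        self.mw_kda = self.mw_kda.reindex(self.counts.index)
        self.n_peptides = self.n_peptides.reindex(self.counts.index)
        if self.mw_kda.isna().any():
            missing = self.mw_kda.index[self.mw_kda.isna()].tolist()[:5]
            raise DataError(f"missing molecular weight for {missing}")
        if (self.mw_kda <= 0).any():
            raise DataError("molecular weights must be > 0")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("spectral counts must be >= 0")
        unassigned = [c for c in self.counts.columns if c not in self.species.index]
        if unassigned:
            raise DataError(f"replicates without species assignment: {unassigned}")
        self.species = self.species.loc[list(self.counts.columns)]

    @property
    def species_labels(self) -> list:
        seen: dict = {}
        for s in self.species:
            seen.setdefault(s, None)
        return list(seen)

    def replicates_of(self, species: str) -> list:
        reps = [c for c in self.counts.columns if self.species[c] == species]
        if not reps:
            raise DataError(f"unknown species label: {species!r}")
        return reps

    def to_frame(self) -> pd.DataFrame:
        """Flat representation used for TSV round-tripping."""
        out = pd.DataFrame(
            {"mw_kda": self.mw_kda, "n_peptides": self.n_peptides}, index=self.counts.index
        )
        return pd.concat([out, self.counts], axis=1)


def default_locus_map(protein_ids) -> dict:
    """Map ``At1g54040.2``-style isoform ids to their AGI locus (suffix stripped)."""
    return {pid: _ISOFORM_RE.match(str(pid)).group(1) for pid in protein_ids}


def combine_isoforms(table: SpectralCountTable, locus_map: dict | None = None) -> SpectralCountTable:
    """Sum spectral counts of isoforms of the same gene locus.

    Counts and peptide numbers are added per replicate; the molecular weight
    of the merged record is the total-count-weighted mean of the isoform
    MWs (falling back to the plain mean when no isoform has any counts).

    Raises
    ------
    DataError
        If ``locus_map`` is given but misses some protein ids.
    """
    if locus_map is None:
        locus_map = default_locus_map(table.counts.index)
    unmapped = [pid for pid in table.counts.index if pid not in locus_map]
    if unmapped:
        raise DataError(f"isoforms missing from locus map: {unmapped}")

    loci = pd.Index([locus_map[pid] for pid in table.counts.index], name="locus")
    order = list(dict.fromkeys(loci))  # first-occurrence order

    grouped_counts = table.counts.groupby(loci, sort=False).sum().loc[order]
    grouped_pep = table.n_peptides.groupby(loci, sort=False).sum().loc[order]

    total = table.counts.sum(axis=1)

    def _mw(group_index):
        w = total.loc[group_index]
        m = table.mw_kda.loc[group_index]
        if w.sum() == 0:
            return float(m.mean())
        return float(np.average(m, weights=w))

    mw = pd.Series(
        {loc: _mw(table.counts.index[loci == loc]) for loc in order}, name="mw_kda"
    ).loc[order]

    return SpectralCountTable(grouped_counts, mw, grouped_pep, table.species.copy())


def filter_proteins(
    table: SpectralCountTable, min_peptides: int = 2, scope: str = "any"
) -> SpectralCountTable:
    """Keep proteins with peptide support and reproducible detection.

    A protein is retained when it has at least ``min_peptides`` distinct
    peptides *and* non-zero counts in every replicate of at least one
    species (``scope="any"``) or of the named species. Row order is
    preserved.
    """
    if scope == "any":
        species_to_check = table.species_labels
    else:
        species_to_check = [scope]
        table.replicates_of(scope)  # raises on unknown label

    complete = pd.Series(False, index=table.counts.index)
    for sp in species_to_check:
        reps = table.replicates_of(sp)
        complete |= (table.counts[reps] > 0).all(axis=1)

    keep = complete & (table.n_peptides >= min_peptides)
    return SpectralCountTable(
        table.counts.loc[keep],
        table.mw_kda.loc[keep],
        table.n_peptides.loc[keep],
        table.species.copy(),
    )


def compute_nsaf(counts, mw) -> pd.Series:
    """NSAF for a single sample: (SpC/MW) normalized to sum to one.

    An all-zero sample yields an all-zero vector with a warning (degenerate
    but survivable, e.g. sparse synthetic data).
    """
    counts = pd.Series(counts, dtype=float)
    mw = pd.Series(mw, dtype=float).reindex(counts.index)
    if (counts < 0).any():
        raise DataError("negative spectral counts")
    if ((counts > 0) & ~(mw > 0)).any():
        raise DataError("molecular weight must be > 0 for every protein with counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        saf = np.where(counts > 0, counts.to_numpy() / mw.to_numpy(), 0.0)
    total = saf.sum()
    if total == 0:
        warnings.warn("sample has zero total spectral counts; NSAF set to 0")
        return pd.Series(0.0, index=counts.index)
    return pd.Series(saf / total, index=counts.index)


def nsaf_table(table: SpectralCountTable) -> pd.DataFrame:
    """Per-replicate NSAF values (NSAF_i): one column per replicate."""
    return pd.DataFrame(
        {rep: compute_nsaf(table.counts[rep], table.mw_kda) for rep in table.counts.columns}
    )


def compute_nsaf_summed(table: SpectralCountTable, species: str) -> pd.Series:
    """Summed-count NSAF (NSAF_S): pool replicate counts of a species, then normalize."""
    reps = table.replicates_of(species)
    pooled = table.counts[reps].sum(axis=1)
    return compute_nsaf(pooled, table.mw_kda)


def nsaf_summed_table(table: SpectralCountTable) -> pd.DataFrame:
    """NSAF_S for every species: loci x species."""
    return pd.DataFrame({sp: compute_nsaf_summed(table, sp) for sp in table.species_labels})


def add_spectral_fraction(table: SpectralCountTable, fraction: float = 0.5) -> SpectralCountTable:
    """Add a pseudo-count to every spectral count.

    Used on the pairwise-test path: pseudo-counted NSAF values are
    approximately normal, justifying t-tests, and log fold changes stay
    finite for proteins absent from one species.
    """
    if not fraction > 0:
        raise DataError("spectral fraction must be > 0")
    return replace(table, counts=table.counts + fraction)
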
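"""TSV / YAML readers and writers for the pipeline's inter-stage contract."""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .proteome import SpectralCountTable

META_COLUMNS = ("locus_id", "mw_kda", "n_peptides")


def read_transcript_tsv(path) -> pd.DataFrame:
    """Genes x arrays log2 matrix; first column holds the locus ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataError(f"empty transcript table: {path}")
    return df


def read_spectral_counts_tsv(path, species_map: dict) -> SpectralCountTable:
    """Spectral-count TSV with columns protein_id, locus_id, mw_kda,
    n_peptides, then one column per replicate; ``species_map`` assigns each
    replicate column to a species."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"spectral count table missing columns {missing}: {path}")
    rep_cols = [c for c in df.columns if c not in META_COLUMNS]
    unmapped = [c for c in rep_cols if c not in species_map]
    if unmapped:
        raise ConfigError(f"replicate columns without species mapping: {unmapped}")
    return SpectralCountTable(
        counts=df[rep_cols],
        mw_kda=df["mw_kda"],
        n_peptides=df["n_peptides"],
        species=pd.Series(species_map),
    )


def read_metabolite_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataError(f"empty metabolite table: {path}")
    return df


def read_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            loaded = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(loaded, dict):
        raise ConfigError(f"config must be a mapping: {path}")
    return loaded


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path
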
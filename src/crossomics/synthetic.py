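"""Multi-species synthetic transcriptome / proteome / metabolome generator.

Emulates a three-species comparative profiling design: per-species
transcript abundances measured on a few arrays, shotgun-proteomics
spectral counts in triplicate, and per-plant glucosinolate
concentrations, with known ground truth for every injected
species-specific regulation event.

Model
-----
Each locus k gets a base log2 abundance b_k ~ N(8, locus_sd^2) shared by
all species. The transcript latent value of species s is
``T[k,s] = b_k + delta[k,s]`` where delta injects the configured
differential regulation. The protein latent value mixes the
(standardized) transcript signal with an independent per-locus noise
vector shared by all species:

    P_z[k] = w * z_k + sqrt(1 - w^2) * eps_k,   w = 2 sin(pi * rho_s / 6)

so that the within-species transcript-protein *rank* correlation equals
the target ``coupling_rho`` in expectation (for a bivariate normal with
Pearson correlation w, Spearman's rho is (6/pi) asin(w/2); the weight
inverts that relation). Injected regulation is added at full magnitude
to both layers.

Spectral counts per replicate are Poisson with rate proportional to
(linear abundance x molecular weight), scaled to the configured total
depth — the construction the NSAF statistic inverts, so NSAF recovers
relative abundance. Optional negative-binomial over-dispersion is off by
default. Metabolite concentrations are species chemotype means with
multiplicative log-normal replicate noise (zero means stay exactly
zero).

Randomness: one root seed spawns independent child streams per component
(truth, transcripts, proteins, counts, metabolites), so regenerating one
component never perturbs another.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .metabolomics import MetaboliteProfile, load_compound_annotations, _packaged
from .proteome import SpectralCountTable

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "generate_dataset",
    "sample_spectral_counts",
    "generate_metabolite_profiles",
    "default_chemotype_means",
]


def default_chemotype_means() -> pd.DataFrame:
    """Bundled per-species glucosinolate chemotype means (umol/g dry wt).

    Patterned on the study system: CH and NZ share their two major
    compounds (allyl and S-2OH3-butenyl) while EX is dominated by
    long-chain methylsulfinylalkyl glucosinolates; only NZ carries the
    extra C4 compounds.
    """
    return _packaged("default_chemotype_means.tsv").set_index("compound")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the emulated design: 3 species, a 9404-gene
    transcript universe, 1489 proteins of which 1074 loci are shared
    with the transcript survey, 3 arrays and 3 proteomic replicates per
    species, 12 metabolite replicates per species, a within-species
    transcript-protein rank correlation of 0.5, and a mean spectral
    depth of 50 counts per protein locus per replicate.
    """

    n_species: int = 3
    n_genes_transcript: int = 9404
    n_genes_protein: int = 1489
    n_shared: int = 1074
    n_array_samples_per_species: int = 3
    n_protein_reps_per_species: int = 3
    n_metabolite_reps_per_species: int = 12
    coupling_rho: float = 0.5
    frac_de: float = 0.1
    de_log2fc: float = 2.0
    count_depth: float | None = None  # expected total SpC per replicate; None -> 50/locus
    noise_sd: float = 0.25  # log2-scale noise on transcript arrays
    locus_sd: float = 1.5  # log2-scale between-locus abundance spread
    metabolite_noise_sd: float = 0.2  # log2-scale multiplicative noise
    overdispersion: float = 0.0  # negative-binomial excess; 0 = Poisson
    seed: int = 0
    species_labels: tuple = ()

    def __post_init__(self):
        counts = {
            "n_species": self.n_species,
            "n_genes_transcript": self.n_genes_transcript,
            "n_genes_protein": self.n_genes_protein,
            "n_shared": self.n_shared,
            "n_array_samples_per_species": self.n_array_samples_per_species,
            "n_protein_reps_per_species": self.n_protein_reps_per_species,
            "n_metabolite_reps_per_species": self.n_metabolite_reps_per_species,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.n_shared > min(self.n_genes_transcript, self.n_genes_protein):
            raise ConfigError("n_shared exceeds one of the parent universes")
        if not 0 <= self.coupling_rho <= 1:
            raise ConfigError("coupling_rho must lie in [0, 1]")
        if not 0 <= self.frac_de <= 1:
            raise ConfigError("frac_de must lie in [0, 1]")
        if self.species_labels and len(self.species_labels) != self.n_species:
            raise ConfigError("species_labels length must equal n_species")

    @property
    def labels(self) -> list:
        if self.species_labels:
            return list(self.species_labels)
        if self.n_species == 3:
            return ["CH", "EX", "NZ"]
        return [f"S{i+1}" for i in range(self.n_species)]

    @property
    def depth(self) -> float:
        return 50.0 * self.n_genes_protein if self.count_depth is None else self.count_depth

    @property
    def mixing_weight(self) -> float:
        """Pearson weight w = 2 sin(pi*rho_s/6) hitting the target Spearman rho."""
        return 2.0 * math.sin(math.pi * self.coupling_rho / 6.0)


@dataclass
class SyntheticDataset:
    """Generated data plus per-locus ground truth."""

    config: SimConfig
    transcript_matrix: pd.DataFrame  # genes x arrays, log2
    spectral_counts: SpectralCountTable
    metabolite_profiles: MetaboliteProfile
    truth: pd.DataFrame  # locus, species, direction, true_log2fc
    latent_transcript: pd.DataFrame  # transcript loci x species, log2
    latent_protein: pd.DataFrame  # protein loci x species, log2

    def write_dir(self, outdir) -> dict:
        """Write the standard input TSVs plus the truth table; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "transcripts": outdir / "transcripts.tsv",
            "spectral_counts": outdir / "spectral_counts.tsv",
            "metabolites": outdir / "metabolites.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.transcript_matrix.rename_axis("locus").to_csv(paths["transcripts"], sep="\t")
        sc = self.spectral_counts.to_frame().rename_axis("protein_id")
        sc.insert(0, "locus_id", sc.index)
        sc.to_csv(paths["spectral_counts"], sep="\t")
        self.metabolite_profiles.concentrations.rename_axis("compound").to_csv(
            paths["metabolites"], sep="\t"
        )
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def make_agi_ids(n: int, start: int = 0) -> list:
    """Deterministic synthetic AGI-style locus codes (AtXgNNNNN), unique."""
    return [f"At{(i % 5) + 1}g{10000 + (i // 5) * 7:05d}" for i in range(start, start + n)]


def sample_spectral_counts(
    latent_abundance,
    mw,
    depth: float,
    rng: np.random.Generator,
    overdispersion: float = 0.0,
) -> np.ndarray:
    """Draw integer spectral counts with E[SpC] proportional to abundance x MW.

    The expected total over all loci equals ``depth``. Because longer
    proteins yield proportionally more spectra, SpC/MW is proportional to
    abundance, which is exactly what NSAF normalization assumes.
    """
    a = np.asarray(latent_abundance, dtype=float)
    m = np.asarray(mw, dtype=float)
    if (m <= 0).any():
        raise DataError("molecular weights must be > 0")
    if (a < 0).any():
        raise DataError("abundances must be >= 0")
    weight = a * m
    total = weight.sum()
    if total == 0:
        return np.zeros_like(a, dtype=np.int64)
    rate = depth * weight / total
    if overdispersion > 0:
        rate = rng.gamma(shape=1.0 / overdispersion, scale=rate * overdispersion)
    return rng.poisson(rate).astype(np.int64)


def generate_metabolite_profiles(
    config: SimConfig,
    species_chemotypes: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> MetaboliteProfile:
    """Per-plant concentrations around per-species chemotype means.

    ``species_chemotypes``: compounds x species mean concentrations
    (defaults to the bundled table). Noise is multiplicative log-normal
    on the log2 scale, so zero means yield exactly zero in every sample
    and ``metabolite_noise_sd=0`` reproduces the means exactly.
    """
    if species_chemotypes is None:
        species_chemotypes = default_chemotype_means()
        if set(config.labels) - set(species_chemotypes.columns):
            raise ConfigError(
                "no bundled chemotype means for species "
                f"{sorted(set(config.labels) - set(species_chemotypes.columns))}; "
                "pass species_chemotypes explicitly"
            )
    if (species_chemotypes.to_numpy() < 0).any():
        raise ConfigError("chemotype means must be >= 0")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])

    cols, data = [], []
    for sp in config.labels:
        means = species_chemotypes[sp].to_numpy(dtype=float)
        for r in range(config.n_metabolite_reps_per_species):
            noise = rng.normal(0.0, config.metabolite_noise_sd, size=means.size)
            data.append(means * np.exp2(noise))
            cols.append(f"{sp}_m{r+1}")
    conc = pd.DataFrame(
        np.column_stack(data), index=species_chemotypes.index, columns=cols
    )
    species = pd.Series({c: c.split("_")[0] for c in cols})
    annotations = load_compound_annotations()
    extra = [c for c in conc.index if c not in annotations.index]
    if extra:  # user-supplied compounds outside the bundled annotation set
        pad = pd.DataFrame(
            {"full_name": extra, "chain_class": "unknown", "alkenyl": 0}, index=extra
        )
        annotations = pd.concat([annotations, pad])
    return MetaboliteProfile(conc, annotations, species)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate one fully coupled multi-omics dataset with ground truth."""
    root = np.random.SeedSequence(config.seed)
    ss_truth, ss_transcript, ss_protein, ss_counts, ss_met = root.spawn(5)
    rng_truth = np.random.default_rng(ss_truth)
    rng_t = np.random.default_rng(ss_transcript)
    rng_p = np.random.default_rng(ss_protein)
    rng_c = np.random.default_rng(ss_counts)
    rng_m = np.random.default_rng(ss_met)

    labels = config.labels
    n_t, n_p, n_sh = config.n_genes_transcript, config.n_genes_protein, config.n_shared
    shared_ids = make_agi_ids(n_sh)
    t_only_ids = make_agi_ids(n_t - n_sh, start=n_sh)
    p_only_ids = make_agi_ids(n_p - n_sh, start=n_t)
    t_ids = shared_ids + t_only_ids
    p_ids = shared_ids + p_only_ids

    # ground truth: which shared loci are regulated, where, and how much
    n_de = int(round(config.frac_de * n_sh))
    de_idx = np.sort(rng_truth.choice(n_sh, size=n_de, replace=False))
    de_species = [labels[i % len(labels)] for i in range(n_de)]
    de_sign = rng_truth.choice([-1.0, 1.0], size=n_de)
    truth = pd.DataFrame(
        {
            "locus": [shared_ids[i] for i in de_idx],
            "species": de_species,
            "direction": np.where(de_sign > 0, "up", "down"),
            "true_log2fc": de_sign * config.de_log2fc,
        }
    )

    # latent log2 abundances
    base_t = rng_t.normal(8.0, config.locus_sd, size=n_t)
    delta = np.zeros((n_sh, len(labels)))
    for j, (idx, sp, sgn) in enumerate(zip(de_idx, de_species, de_sign)):
        delta[idx, labels.index(sp)] = sgn * config.de_log2fc

    latent_t = np.tile(base_t[:, None], (1, len(labels)))
    latent_t[:n_sh, :] += delta

    # The mixing noise is one per-locus vector shared by all species: species
    # protein profiles then differ only through the injected regulation, so
    # null data (frac_de=0) really is null for the between-species tests.
    w = config.mixing_weight
    z = (base_t[:n_sh] - base_t[:n_sh].mean()) / base_t[:n_sh].std()
    eps = rng_p.normal(0.0, 1.0, size=n_sh)
    pz_shared = w * z + math.sqrt(max(0.0, 1.0 - w**2)) * eps
    latent_p_shared = 8.0 + config.locus_sd * pz_shared[:, None] + delta
    base_p_only = rng_p.normal(8.0, config.locus_sd, size=n_p - n_sh)
    latent_p = np.vstack([latent_p_shared, np.tile(base_p_only[:, None], (1, len(labels)))])

    # observed transcript arrays
    t_cols, t_data = [], []
    for sj, sp in enumerate(labels):
        for r in range(config.n_array_samples_per_species):
            t_data.append(latent_t[:, sj] + rng_t.normal(0.0, config.noise_sd, size=n_t))
            t_cols.append(f"{sp}_a{r+1}")
    transcript_matrix = pd.DataFrame(np.column_stack(t_data), index=t_ids, columns=t_cols)

    # protein metadata and spectral counts
    mw = np.clip(rng_p.lognormal(math.log(40.0), 0.45, size=n_p), 5.0, 250.0)
    n_peptides = 1 + rng_p.poisson(3.0, size=n_p)
    c_cols, c_data = [], []
    # replicate-to-replicate variability comes from the count model alone:
    # Poisson by default, negative-binomial when overdispersion > 0
    for sj, sp in enumerate(labels):
        for r in range(config.n_protein_reps_per_species):
            counts = sample_spectral_counts(
                np.exp2(latent_p[:, sj]), mw, config.depth, rng_c, config.overdispersion
            )
            c_data.append(counts)
            c_cols.append(f"{sp}_r{r+1}")
    counts_df = pd.DataFrame(np.column_stack(c_data), index=p_ids, columns=c_cols)
    species_of_rep = pd.Series({c: c.split("_")[0] for c in c_cols})
    spectral = SpectralCountTable(
        counts_df,
        pd.Series(mw, index=p_ids, name="mw_kda"),
        pd.Series(n_peptides, index=p_ids, name="n_peptides"),
        species_of_rep,
    )

    metabolites = generate_metabolite_profiles(config, rng=rng_m)

    return SyntheticDataset(
        config=config,
        transcript_matrix=transcript_matrix,
        spectral_counts=spectral,
        metabolite_profiles=metabolites,
        truth=truth,
        latent_transcript=pd.DataFrame(latent_t, index=t_ids, columns=labels),
        latent_protein=pd.DataFrame(latent_p, index=p_ids, columns=labels),
    )
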
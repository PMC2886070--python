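"""End-to-end orchestration: simulate/load -> NSAF -> DE -> concordance ->
chemotype, with a provenance manifest.

Stages communicate through TSV files in the output directory, so each
stage is independently re-runnable from its predecessors' outputs. One
root seed is fanned out to the simulation and permutation streams; a
fixed config therefore reproduces every stochastic output bit for bit.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import common_gene_set, correlation_matrix, overlap_analysis, permutation_overlap_pvalue
from .diffexpr import (
    build_design,
    fit_transcript_contrasts,
    protein_group_test,
    protein_pairwise_test,
    study_contrasts,
)
from .errors import ConfigError, PipelineError
from .io import read_metabolite_tsv, read_spectral_counts_tsv, read_transcript_tsv, read_yaml, write_tsv
from .metabolomics import (
    MetaboliteProfile,
    cluster_profiles,
    evaluate_predictions,
    hydrolysis_partition,
    load_chemotype_rules,
    load_compound_annotations,
    load_hydrolysis_table,
    predict_chemotype,
    to_proportions,
)
from .proteome import add_spectral_fraction, combine_isoforms, filter_proteins, nsaf_summed_table, nsaf_table
from .synthetic import SimConfig, generate_dataset

log = logging.getLogger("crossomics")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; build from YAML via :meth:`from_yaml`."""

    outdir: Path
    seed: int = 0
    alpha: float = 0.05
    spectral_fraction: float = 0.5
    n_perm: int = 10000
    min_peptides: int = 2
    simulate: SimConfig | None = None
    transcript_tsv: Path | None = None
    protein_tsv: Path | None = None
    metabolite_tsv: Path | None = None
    species_map: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None, outdir=None) -> "RunConfig":
        raw = read_yaml(path)
        return cls.from_dict(raw, seed=seed, outdir=outdir)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None, outdir=None) -> "RunConfig":
        cfg_seed = seed if seed is not None else int(raw.get("seed", 0))
        out = Path(outdir if outdir is not None else raw.get("outdir", "crossomics_out"))
        sim = None
        if "simulate" in raw:
            sim_kwargs = dict(raw["simulate"] or {})
            sim_kwargs.setdefault("seed", cfg_seed)
            try:
                sim = SimConfig(**sim_kwargs)
            except TypeError as exc:
                raise ConfigError(f"bad simulate block: {exc}") from exc
        cfg = cls(
            outdir=out,
            seed=cfg_seed,
            alpha=float(raw.get("alpha", 0.05)),
            spectral_fraction=float(raw.get("spectral_fraction", 0.5)),
            n_perm=int(raw.get("n_perm", 10000)),
            min_peptides=int(raw.get("min_peptides", 2)),
            simulate=sim,
            transcript_tsv=_maybe_path(raw.get("transcript_tsv")),
            protein_tsv=_maybe_path(raw.get("protein_tsv")),
            metabolite_tsv=_maybe_path(raw.get("metabolite_tsv")),
            species_map=dict(raw.get("species_map", {})),
            raw=raw,
        )
        if cfg.simulate is None:
            missing = [n for n in ("transcript_tsv", "protein_tsv") if getattr(cfg, n) is None]
            if missing:
                raise ConfigError(
                    f"config needs either a simulate block or {', '.join(missing)}"
                )
            for name in ("transcript_tsv", "protein_tsv"):
                p = getattr(cfg, name)
                if not Path(p).exists():
                    raise ConfigError(f"{name} does not exist: {p}")
        return cfg

    def config_hash(self) -> str:
        canon = dict(self.raw) or {
            "seed": self.seed,
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "simulate": bool(self.simulate),
        }
        blob = yaml.safe_dump(canon, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _maybe_path(p):
    return None if p is None else Path(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    root_ss = np.random.SeedSequence(config.seed)
    sim_ss, perm_ss = root_ss.spawn(2)

    # ---- stage: data -------------------------------------------------
    stage = "data"
    try:
        if config.simulate is not None:
            log.info("simulating dataset (seed=%d)", config.simulate.seed)
            dataset = generate_dataset(config.simulate)
            outputs.update(dataset.write_dir(outdir / "simulated"))
            transcripts = dataset.transcript_matrix
            spectral = dataset.spectral_counts
            metabolites = dataset.metabolite_profiles
        else:
            transcripts = read_transcript_tsv(config.transcript_tsv)
            spectral = read_spectral_counts_tsv(config.protein_tsv, config.species_map)
            metabolites = None
            if config.metabolite_tsv is not None:
                conc = read_metabolite_tsv(config.metabolite_tsv)
                ann = load_compound_annotations()
                extra = [c for c in conc.index if c not in ann.index]
                if extra:
                    ann = pd.concat(
                        [ann, pd.DataFrame({"full_name": extra, "chain_class": "unknown",
                                            "alkenyl": 0}, index=extra)]
                    )
                sp = pd.Series({c: c.rsplit("_", 1)[0] for c in conc.columns})
                metabolites = MetaboliteProfile(conc, ann, sp)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: nsaf -------------------------------------------------
    stage = "nsaf"
    try:
        merged = combine_isoforms(spectral)
        filtered = filter_proteins(merged, min_peptides=config.min_peptides, scope="any")
        log.info("nsaf: %d proteins -> %d loci -> %d after filtering",
                 len(spectral.counts), len(merged.counts), len(filtered.counts))
        nsaf_i = nsaf_table(filtered)
        nsaf_s = nsaf_summed_table(filtered)
        fraction_table = add_spectral_fraction(filtered, config.spectral_fraction)
        nsaf_frac = nsaf_table(fraction_table)
        nsaf_s_frac = nsaf_summed_table(fraction_table)
        outputs["nsaf_per_replicate"] = write_tsv(nsaf_i.rename_axis("locus"), outdir / "nsaf_per_replicate.tsv")
        outputs["nsaf_summed"] = write_tsv(nsaf_s.rename_axis("locus"), outdir / "nsaf_summed.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: de ---------------------------------------------------
    stage = "de"
    try:
        species_of_array = pd.Series(
            {c: c.rsplit("_", 1)[0] for c in transcripts.columns}
        )
        labels = list(dict.fromkeys(species_of_array))
        contrasts = study_contrasts(labels)
        design = build_design(species_of_array)[labels]
        de_t = fit_transcript_contrasts(transcripts, design, contrasts, alpha=config.alpha)

        frames = []
        for spec in contrasts:
            if spec.kind == "group":
                frames.append(
                    protein_group_test(
                        nsaf_i, filtered.species, spec.target, spec.others,
                        alpha=config.alpha, nsaf_fc=nsaf_frac,
                    )
                )
            else:
                frames.append(
                    protein_pairwise_test(
                        nsaf_frac, filtered.species, spec.target, spec.others[0],
                        alpha=config.alpha,
                    )
                )
        de_p = pd.concat(frames, ignore_index=True)
        outputs["de_transcript"] = write_tsv(de_t, outdir / "de_transcript.tsv", index=False)
        outputs["de_protein"] = write_tsv(de_p, outdir / "de_protein.tsv", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: concord ----------------------------------------------
    stage = "concord"
    try:
        common = common_gene_set(transcripts.index, filtered.counts.index)
        t_means = pd.DataFrame(
            {sp: transcripts[[c for c in transcripts.columns if species_of_array[c] == sp]].mean(axis=1)
             for sp in labels}
        )
        p_log2 = np.log2(nsaf_s_frac)
        corr = correlation_matrix(t_means, p_log2, common)
        outputs["correlations"] = write_tsv(corr.to_frame(), outdir / "correlations.tsv")

        perm_rng = np.random.default_rng(perm_ss)
        rows = []
        from .diffexpr import call_regulated

        calls_t = call_regulated(de_t, alpha=config.alpha)
        calls_p = call_regulated(de_p, alpha=config.alpha)
        for spec in contrasts:
            for direction in ("up", "down"):
                name = f"{spec.name}:{direction}"
                res = overlap_analysis(
                    calls_t[spec.name][direction], calls_p[spec.name][direction],
                    common, contrast=name,
                )
                if res.a and res.b:
                    res.p_perm = permutation_overlap_pvalue(
                        res.a, res.b, res.k, len(common), n_perm=config.n_perm, rng=perm_rng
                    )
                    res.n_perm = config.n_perm
                rows.append(
                    {"contrast": name, "a": res.a, "b": res.b, "k": res.k,
                     "upper_pct": res.upper_pct_display, "lower_pct": res.lower_pct_display,
                     "p_perm": res.p_perm,
                     "significant": bool(res.p_perm is not None and res.p_perm < config.alpha)}
                )
        overlap_df = pd.DataFrame(rows)
        outputs["overlap"] = write_tsv(overlap_df, outdir / "overlap.tsv", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: chemotype ---------------------------------------------
    stage = "chemotype"
    try:
        if metabolites is not None:
            props = to_proportions(metabolites)
            tree = cluster_profiles(props)
            (outdir / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
            outputs["dendrogram"] = outdir / "dendrogram.nwk"

            hydrolysis = load_hydrolysis_table()
            parts = []
            for sp in sorted(set(hydrolysis["species"])):
                part = hydrolysis_partition(hydrolysis, sp)
                if part["compounds"] is not None:
                    parts.append(part["compounds"])
            if parts:
                outputs["hydrolysis_partition"] = write_tsv(
                    pd.concat(parts, ignore_index=True), outdir / "hydrolysis_partition.tsv",
                    index=False,
                )

            rules = load_chemotype_rules()
            preds = predict_chemotype(
                {"T": de_t, "P": de_p}, rules, alpha=config.alpha, species_universe=labels
            )
            report = evaluate_predictions(preds, metabolites, hydrolysis, alpha=config.alpha)
            outputs["chemotype_predictions"] = write_tsv(
                report["predictions"], outdir / "chemotype_predictions.tsv", index=False
            )
            accuracy = report["accuracy"]
        else:
            log.info("no metabolite data; chemotype stage skipped")
            accuracy = {}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "package": "crossomics",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "alpha": config.alpha,
        "n_perm": config.n_perm,
        "prediction_accuracy_by_layer": accuracy,
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))} for name, p in outputs.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
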
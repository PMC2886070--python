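"""Glucosinolate chemotype analysis.

Three tasks: (1) hierarchical clustering of per-plant glucosinolate
profiles (proportions of total content, Euclidean distance, Ward
linkage); (2) partitioning of glucosinolate hydrolysis products into
isothiocyanate vs nitrile/epithionitrile fractions; (3) a small rule
engine that turns differential expression of glucosinolate-pathway loci
(side-chain elongation: MAM1/MAM-I/MAM-D; side-chain modification:
AOP2/AOP3; hydrolysis specifiers: ESP/ESM1) into chemotype predictions,
and scores those predictions against measured profiles.

Hydrolysis chemistry in brief: damaged tissue releases myrosinase, which
hydrolyses glucosinolates to unstable intermediates; by default these
rearrange to isothiocyanates, but epithiospecifier protein (ESP) diverts
them to nitriles and epithionitriles, and ESM1 antagonises ESP.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .concordance import round_half_up
from .diffexpr import call_regulated
from .errors import ConfigError, DataError

__all__ = [
    "MetaboliteProfile",
    "LinkageTree",
    "to_proportions",
    "cluster_profiles",
    "hydrolysis_partition",
    "predict_chemotype",
    "evaluate_predictions",
    "load_compound_annotations",
    "load_chemotype_rules",
    "load_hydrolysis_table",
]

ISOTHIOCYANATE = "isothiocyanate"
NITRILE = "nitrile/epithionitrile"

_CLASS_SUM = {
    "alkenyl_higher": ("alkenyl", 1),
    "hydroxyalkyl_higher": ("chain_class", "hydroxyalkyl"),
    "c4_higher": ("chain_class", "C4"),
}
_HYDROLYSIS_CLAIM = {"nitriles": NITRILE, "isothiocyanates": ISOTHIOCYANATE}


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("crossomics").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_compound_annotations() -> pd.DataFrame:
    """Bundled annotations for the fourteen profiled glucosinolates."""
    return _packaged("compound_annotations.tsv").set_index("compound")


def load_chemotype_rules() -> pd.DataFrame:
    """Bundled rule table mapping pathway-locus regulation to phenotype claims."""
    return _packaged("chemotype_rules.tsv")


def load_hydrolysis_table() -> pd.DataFrame:
    """Bundled glucosinolate hydrolysis-product measurements (nmol/g fresh wt)."""
    return _packaged("hydrolysis_products.tsv")


@dataclass
class MetaboliteProfile:
    """Compound x sample concentration matrix with compound annotations."""

    concentrations: pd.DataFrame  # compounds x samples, >= 0
    annotations: pd.DataFrame  # index compound: chain_class, alkenyl
    species: pd.Series  # sample -> species label
    unit: str = "umol/g dry wt"

    def __post_init__(self):
        if (self.concentrations.to_numpy() < 0).any():
            raise DataError("metabolite concentrations must be >= 0")
        missing = [c for c in self.concentrations.index if c not in self.annotations.index]
        if missing:
            raise DataError(f"compounds without annotation: {missing}")

    def class_sums(self, column: str, value) -> pd.DataFrame:
        """Per-sample total concentration of the compounds in one class."""
        members = self.annotations.index[self.annotations[column] == value]
        members = [c for c in self.concentrations.index if c in set(members)]
        return self.concentrations.loc[members].sum(axis=0)


def to_proportions(profile) -> pd.DataFrame:
    """Per-sample compound proportions (columns sum to one).

    Samples with zero total content are dropped with a warning. Accepts a
    :class:`MetaboliteProfile` or a bare compound x sample DataFrame.
    """
    conc = profile.concentrations if isinstance(profile, MetaboliteProfile) else profile
    if (conc.to_numpy() < 0).any():
        raise DataError("negative concentrations")
    totals = conc.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"dropping zero-total samples: {empty}")
        conc = conc.drop(columns=empty)
        totals = totals.drop(empty)
    return conc / totals


@dataclass
class LinkageTree:
    """Agglomerative merge tree: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = fmt(root.left, root.dist)
        right = fmt(root.right, root.dist)
        return f"({left},{right});"

    def cut(self, n_clusters: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.labels)


def cluster_profiles(proportions: pd.DataFrame) -> LinkageTree:
    """Ward linkage on Euclidean distances between samples (columns).

    Merge heights follow the scipy convention: the height of a merge is
    sqrt(2 * increase in within-cluster sum of squares).
    """
    if proportions.shape[1] < 2:
        raise DataError("need at least two samples to cluster")
    if proportions.columns.duplicated().any():
        dups = proportions.columns[proportions.columns.duplicated()].tolist()
        raise DataError(f"duplicate sample ids: {dups}")
    X = proportions.T.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="ward")
    return LinkageTree(Z, list(proportions.columns))


def hydrolysis_partition(table: pd.DataFrame, species: str) -> dict:
    """Percent of total hydrolysis products per compound and per class.

    ``table`` columns: species, parent_glucosinolate, compound,
    product_class, mean, sd. Compound percentages are
    100 * mean / species total, displayed rounded half-up to one decimal.
    Class percentages come in two variants: the sum of full-precision
    compound percentages and the sum of the *rounded* ones (printed
    summary tables conventionally add up the rounded values).
    """
    sub = table[table["species"] == species]
    if sub.empty:
        raise DataError(f"no hydrolysis data for species {species!r}")
    total = float(sub["mean"].sum())
    if total <= 0:
        warnings.warn(f"zero hydrolysis total for {species}; percentages undefined")
        return {"species": species, "total": 0.0, "compounds": None, "classes": None}
    comp = sub.assign(
        pct=100.0 * sub["mean"] / total,
        pct_display=[round_half_up(100.0 * m / total, 1) for m in sub["mean"]],
    )
    classes = comp.groupby("product_class").agg(
        pct_full=("pct", "sum"), pct_rounded_sum=("pct_display", "sum")
    )
    classes["pct_rounded_sum"] = [round_half_up(v, 1) for v in classes["pct_rounded_sum"]]
    return {
        "species": species,
        "total": total,
        "compounds": comp.reset_index(drop=True),
        "classes": classes,
    }


_RULE_COLUMNS = [
    "rule_id", "locus", "symbol", "layer", "contrast", "direction",
    "prediction_type", "species", "versus",
]


def predict_chemotype(
    de_tables: dict, rules: pd.DataFrame, alpha: float = 0.05, species_universe=None
) -> pd.DataFrame:
    """Fire chemotype rules against differential-expression calls.

    Parameters
    ----------
    de_tables : dict
        Layer label ("T" for transcripts, "P" for proteins) -> tidy DE
        table as produced by the differential_expression functions.
    rules : DataFrame
        One row per rule; required columns: rule_id, locus, symbol,
        layer, contrast, direction (up/down), prediction_type
        (alkenyl_higher | hydroxyalkyl_higher | c4_higher | nitriles |
        isothiocyanates), species (the predicted winner), versus
        (comma-separated comparison species, or "rest").

    Returns one row per fired rule; a rule fires when its locus is called
    in the stated direction in the stated contrast of its layer. Two
    fired "higher" claims about the same compound class with swapped
    winner/loser roles are both kept and flagged ``conflict=True``.
    """
    missing = [c for c in _RULE_COLUMNS if c not in rules.columns]
    if missing:
        raise ConfigError(f"malformed rule table, missing columns: {missing}")
    bad_dir = set(rules["direction"]) - {"up", "down"}
    if bad_dir:
        raise ConfigError(f"malformed rule direction(s): {sorted(bad_dir)}")

    calls = {
        layer: call_regulated(tab, alpha=alpha) for layer, tab in de_tables.items()
    }
    if species_universe is None:
        species_universe = sorted(
            {r["species"] for _, r in rules.iterrows()}
            | {s for _, r in rules.iterrows() for s in _versus_list(r, None) if s != "rest"}
        )

    fired = []
    for _, rule in rules.iterrows():
        layer_calls = calls.get(rule["layer"], {})
        contrast_calls = layer_calls.get(rule["contrast"])
        if contrast_calls is None:
            continue  # contrast absent from the DE tables -> no prediction
        if rule["locus"] in contrast_calls[rule["direction"]]:
            versus = _versus_list(rule, species_universe)
            fired.append({**rule.to_dict(), "versus_expanded": tuple(versus)})

    out = pd.DataFrame(fired)
    if out.empty:
        return pd.DataFrame(columns=_RULE_COLUMNS + ["versus_expanded", "conflict"])
    out["conflict"] = False
    for i, ri in out.iterrows():
        for j, rj in out.iterrows():
            if i >= j or ri["prediction_type"] != rj["prediction_type"]:
                continue
            if ri["prediction_type"] not in _CLASS_SUM:
                continue
            if ri["species"] in rj["versus_expanded"] and rj["species"] in ri["versus_expanded"]:
                out.loc[i, "conflict"] = True
                out.loc[j, "conflict"] = True
    return out


def _versus_list(rule, species_universe):
    raw = [v.strip() for v in str(rule["versus"]).split(",") if v.strip()]
    if raw == ["rest"]:
        if species_universe is None:
            return ["rest"]
        return [s for s in species_universe if s != rule["species"]]
    return raw


def evaluate_predictions(
    predictions: pd.DataFrame,
    profile: MetaboliteProfile | None,
    hydrolysis: pd.DataFrame | None,
    alpha: float = 0.05,
) -> dict:
    """Score each fired prediction against measured chemotypes.

    Compound-class claims ("X higher in A than B") are tested by a Welch
    t-test on per-sample class totals: supported when the winner's mean
    is higher and p < alpha, contradicted when significantly lower, and
    untestable otherwise (ties, all-zero classes, missing data).
    Hydrolysis claims are judged by the dominant product class (> 50% of
    total products): supported on a match, contradicted on the opposite
    dominance, untestable when the species was not assayed.

    Returns ``{"predictions": DataFrame with verdict/p/means columns,
    "accuracy": {layer: supported / (supported + contradicted)}}``.
    """
    from scipy import stats as _stats

    rows = []
    for _, pred in predictions.iterrows():
        verdict, pval, mean_w, mean_v = "untestable", np.nan, np.nan, np.nan
        ptype = pred["prediction_type"]
        if ptype in _CLASS_SUM and profile is not None:
            column, value = _CLASS_SUM[ptype]
            sums = profile.class_sums(column, value)
            winner = sums[profile.species == pred["species"]]
            losers = sums[profile.species.isin(pred["versus_expanded"])]
            if len(winner) >= 2 and len(losers) >= 2:
                mean_w, mean_v = float(winner.mean()), float(losers.mean())
                if mean_w == mean_v:
                    verdict = "untestable"  # tie, including both-all-zero
                else:
                    with np.errstate(invalid="ignore"), warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        _, pval = _stats.ttest_ind(winner, losers, equal_var=False)
                    pval = float(pval) if np.isfinite(pval) else 1.0
                    if pval < alpha:
                        verdict = "supported" if mean_w > mean_v else "contradicted"
        elif ptype in _HYDROLYSIS_CLAIM and hydrolysis is not None:
            if pred["species"] in set(hydrolysis["species"]):
                part = hydrolysis_partition(hydrolysis, pred["species"])
                classes = part["classes"]
                claimed = _HYDROLYSIS_CLAIM[ptype]
                share = float(classes["pct_full"].get(claimed, 0.0))
                verdict = "supported" if share > 50.0 else "contradicted"
                mean_w = share
        rows.append(
            {**pred.to_dict(), "verdict": verdict, "p_value": pval,
             "winner_mean": mean_w, "versus_mean": mean_v}
        )

    scored = pd.DataFrame(rows)
    accuracy = {}
    if not scored.empty:
        for layer, sub in scored.groupby("layer"):
            n_sup = int((sub["verdict"] == "supported").sum())
            n_con = int((sub["verdict"] == "contradicted").sum())
            accuracy[layer] = n_sup / (n_sup + n_con) if (n_sup + n_con) else np.nan
    return {"predictions": scored, "accuracy": accuracy}
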
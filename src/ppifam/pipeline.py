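"""Full pipeline orchestration from a flat config.

Stage order: clean/filter the edge list -> family-labelled main component
-> topology (centralities, hub enrichment) -> k-core profile -> hub
co-expression (if expression inputs given) -> clique-based complex
prediction with optional reference matching and decoy evaluation. Each
stage writes its TSV report; the aggregated numbers land in summary.json
together with the seeds and parameters used, so two runs with the same
config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cliquepred, coexpr, kcore, netio, topology

log = logging.getLogger("ppifam")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run. Expression and reference inputs
    are optional; stages needing them are skipped with a warning."""

    network: str
    family: str
    out_dir: str
    expression: str | None = None
    sample_map: str | None = None
    reference: str | None = None
    confidence_quantile: float | None = 0.75
    hub_cutoffs: tuple[int, ...] = (5, 10, 15)
    primary_hub_cutoff: int = 5
    min_complex_size: int = 3
    merge_thresholds: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    omega_cutoffs: tuple[float, ...] = tuple(
        float(np.round(c, 1)) for c in np.arange(0.0, 1.01, 0.1)
    )
    mmr_omega_cutoff: float = 0.2
    n_shuffles: int = 20
    decoy_seed: int = 0
    n_decoys_per_complex: int = 1
    compute_path_centralities: bool = True
    k_range: tuple[int, int] | None = None

    def validate(self) -> None:
        for label in ("network", "family"):
            p = getattr(self, label)
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} input not found: {p}")
        for label in ("expression", "sample_map", "reference"):
            p = getattr(self, label)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} input not found: {p}")


_TUPLE_FIELDS = {"hub_cutoffs", "merge_thresholds", "omega_cutoffs", "k_range"}


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a flat key-value (YAML mapping) config; kwargs override keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    for key in _TUPLE_FIELDS & set(raw):
        if raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all applicable stages; returns the summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "config": _config_dict(config)}

    # -- netio ---------------------------------------------------------
    interactions = netio.read_edge_list(config.network)
    summary["cleaning"] = dict(interactions.provenance)
    if config.confidence_quantile is not None:
        filtered, threshold = netio.filter_high_confidence(
            interactions, config.confidence_quantile
        )
        summary["confidence_filter"] = {
            "quantile": config.confidence_quantile,
            "threshold": threshold,
            "n_retained": len(filtered),
            "n_total": len(interactions),
            "retained_percent": netio.retained_percent(
                len(filtered), len(interactions)
            ),
        }
        netio.write_edge_list(filtered, out / "filtered_edges.tsv")
        active = filtered
    else:
        active = interactions
    family_ids = netio.read_family_list(config.family)
    g_full = netio.build_network(active, family_ids)
    g = netio.main_component(g_full)
    fam = netio.family_flags(g)
    summary["network"] = {
        "n_nodes": g_full.number_of_nodes(),
        "n_edges": g_full.number_of_edges(),
        "n_family": sum(fam.values()),
        "family_ids_absent": g_full.graph["family_ids_absent"],
        "main_component_nodes": g.number_of_nodes(),
        "main_component_occupation": g.graph["main_component_occupation"],
    }

    # -- topology ------------------------------------------------------
    degrees = topology.degree_all(g)
    k_values = kcore.kcore_decompose(g)
    metrics = topology.node_metrics_table(
        g,
        hub_cutoff=config.primary_hub_cutoff,
        k_values=k_values,
        include_paths=config.compute_path_centralities,
    )
    metrics.to_csv(out / "node_metrics.tsv", sep="\t", index=False)
    enrichment_rows = []
    for cutoff in config.hub_cutoffs:
        hubs = topology.classify_hubs(degrees, cutoff)
        res = topology.enrichment_odds_ratio(hubs, fam)
        enrichment_rows.append(
            {
                "hub_cutoff": cutoff,
                "family_hub": res.counts[0],
                "family_nonhub": res.counts[1],
                "other_hub": res.counts[2],
                "other_nonhub": res.counts[3],
                "odds_ratio": res.odds_ratio,
                "chi2": res.chi2,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    pd.DataFrame(enrichment_rows).to_csv(
        out / "hub_enrichment.tsv", sep="\t", index=False
    )
    summary["hub_enrichment"] = enrichment_rows
    metric_cols = [
        c
        for c in ("degree", "betweenness", "closeness", "stress", "clustering")
        if c in metrics.columns
    ]
    comparisons = {}
    for col in metric_cols:
        values = dict(zip(metrics["node"], metrics[col]))
        cmp_res = topology.compare_groups(values, fam)
        comparisons[col] = vars(cmp_res)
    summary["group_comparisons"] = comparisons

    # -- kcore ---------------------------------------------------------
    profile, k_comparison = kcore.family_core_profile(k_values, fam)
    profile.to_csv(out / "core_profile.tsv", sep="\t", index=False)
    kcore.layer_table(k_values, fam).to_csv(
        out / "core_layers.tsv", sep="\t", index=False
    )
    trend = kcore.core_trend_fit(profile, config.k_range)
    summary["kcore"] = {
        "median_k_family": k_comparison.median_family,
        "median_k_other": k_comparison.median_other,
        "fold_change": k_comparison.fold_change,
        "p_value": k_comparison.p_value,
        "trend": vars(trend),
    }

    # -- coexpr --------------------------------------------------------
    profiles = None
    if config.expression and config.sample_map:
        matrix = coexpr.read_expression_matrix(config.expression)
        sample_map = coexpr.read_sample_map(config.sample_map)
        profiles = coexpr.build_profiles(matrix, sample_map)
        hubs = topology.classify_hubs(degrees, config.primary_hub_cutoff)
        observed = coexpr.hub_average_pcc(g, hubs, profiles)
        hub_df = pd.DataFrame(
            [vars(h) for h in observed],
            columns=["hub", "family", "n_partners_scored", "average_pcc"],
        )
        hub_df.to_csv(out / "hub_coexpression.tsv", sep="\t", index=False)
        null = coexpr.shuffled_null(
            g, hubs, profiles, n_shuffles=config.n_shuffles,
            seed=config.decoy_seed,
        )
        fam_avg = hub_df.loc[hub_df["family"], "average_pcc"]
        other_avg = hub_df.loc[~hub_df["family"], "average_pcc"]
        summary["coexpression"] = {
            "n_hubs_scored": len(hub_df),
            "median_family": float(fam_avg.median()) if len(fam_avg) else None,
            "median_other": float(other_avg.median()) if len(other_avg) else None,
            "null_median": float(np.median(null)) if null.size else None,
            "observed_median": float(hub_df["average_pcc"].median())
            if len(hub_df)
            else None,
        }
    else:
        log.warning("expression inputs missing: co-expression stage skipped")

    # -- cliquepred ----------------------------------------------------
    sub = cliquepred.family_neighborhood(g)
    cliques = cliquepred.maximal_cliques(sub)
    predicted = cliquepred.filter_cliques(
        cliques, fam, min_size=config.min_complex_size
    )
    cliquepred.write_complexes(predicted, out / "predicted_complexes.tsv")
    merged_sets = {}
    for threshold in config.merge_thresholds:
        name = f"M{int(round(threshold * 10)):02d}"
        merged_sets[name] = cliquepred.merge_cliques(predicted, threshold)
    summary["complexes"] = {
        "n_maximal_cliques": len(cliques),
        "n_predicted": len(predicted),
        "set_sizes": {k: len(v) for k, v in merged_sets.items()},
    }
    if config.reference:
        reference = cliquepred.read_complexes(config.reference)
        match_rows = []
        for name, cset in merged_sets.items():
            if not cset:
                continue
            for report in cliquepred.match_reference(
                cset, reference, config.omega_cutoffs
            ):
                match_rows.append(
                    {
                        "set": name,
                        "omega_cutoff": report.omega_cutoff,
                        "n_reference_matched": report.n_reference_matched,
                        "mmr": report.mmr,
                    }
                )
        match_df = pd.DataFrame(match_rows)
        match_df.to_csv(out / "match_report.tsv", sep="\t", index=False)
        final = merged_sets.get("M10", predicted)
        summary["matching"] = {
            "n_reference": len(reference),
            "final_set": "M10",
            "per_cutoff": match_df[match_df["set"] == "M10"].to_dict("records"),
            "mmr_at_default": cliquepred.mmr(
                final, reference, config.mmr_omega_cutoff
            ),
        }
    else:
        log.warning("no reference set: matching stage skipped")
    if profiles is not None and predicted:
        final = merged_sets.get("M10", predicted)
        scores = cliquepred.complex_coexpression(final, profiles)
        decoys = cliquepred.generate_decoys(
            final,
            sorted(g.nodes),
            seed=config.decoy_seed,
            n_per_complex=config.n_decoys_per_complex,
        )
        decoy_scores = cliquepred.complex_coexpression(decoys, profiles)
        score_df = pd.DataFrame(
            [vars(s) | {"set": "predicted"} for s in scores]
            + [vars(s) | {"set": "decoy"} for s in decoy_scores]
        )
        score_df.to_csv(out / "complex_coexpression.tsv", sep="\t",
                        index=False)
        med_pred = float(np.median([s.score for s in scores])) if scores else None
        med_decoy = (
            float(np.median([s.score for s in decoy_scores]))
            if decoy_scores
            else None
        )
        summary["complex_coexpression"] = {
            "median_predicted": med_pred,
            "median_decoy": med_decoy,
            "fold_change": (med_pred / med_decoy)
            if med_pred is not None and med_decoy not in (None, 0.0)
            else None,
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return summary


def _config_dict(config: PipelineConfig) -> dict:
    return {k: _jsonable(v) for k, v in vars(config).items()}


def _jsonable(value):
    if isinstance(value, (tuple, set, frozenset)):
        return list(value)
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    return value
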
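"""End-to-end orchestration: simulate/ingest -> normalize -> select genes ->
cluster -> classify subtypes -> mutation statistics -> responder report.

One structured config drives every stage; a manifest records the config
hash, seed, per-stage outputs and their checksums, so a rerun with the
same config and seed yields identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import io as dio
from .bccp import SubtypePredictor, confusion_and_rates, loocv
from .cluster import CentroidLinkageClustering, assignment_table
from .containers import ValidationError
from .diffexpr import differential_expression, select_genes
from .mutstats import chi_square_2x2, compare_burden, mutation_burden, \
    mutation_frequency_table
from .normalize import normalize_rnaseq, pool_datasets, zscore_within_dataset
from .responders import DEFAULT_PATHWAY_RESPONSE_RATE, \
    subtype_fractions_from_labels, summarize_groups
from .simulate import SimulationConfig, simulate_cohorts, write_fixture

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},           # SimulationConfig overrides
    "normalize": {"pseudocount": 1.0, "log2_first": False},
    "diffexpr": {"group_column": "cluster", "p_threshold": 0.05,
                 "fc_threshold": None},
    "cluster": {"k": 2},
    "bccp": {"alpha": 0.001, "top_n": 200, "threshold": 0.5,
             "node_order": ["EBV", "MSI", "GS"], "cv": "none"},
    "mutstats": {"yates": False, "breakpoints": [100, 500],
                 "driver_genes": ["PIK3CA", "CDH1"]},
    "responders": {"driver_gene": "PIK3CA",
                   "pathway_response_rate": DEFAULT_PATHWAY_RESPONSE_RATE,
                   "rates": None},
}


def merge_config(overrides: dict | None) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: dict | None, outdir: str | Path) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    config = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config),
                      "seed": config["seed"], "stages": {}, "metrics": {},
                      "status": "incomplete"}
    manifest_path = outdir / "manifest.json"

    def record(stage: str, paths: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in paths.items()}
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    try:
        # 1. simulate
        sim_kwargs = dict(config["simulate"])
        sim_kwargs.setdefault("seed", config["seed"])
        if "cohorts" in sim_kwargs:
            sim_kwargs["cohorts"] = {c: dict(v) for c, v in sim_kwargs["cohorts"].items()}
        fixture = simulate_cohorts(SimulationConfig(**sim_kwargs))
        fixture_dir = outdir / "fixture"
        record("simulate", write_fixture(fixture, fixture_dir))
        annotation = fixture.annotation.set_index("sample_id")

        # 2. normalize per cohort, standardize, pool
        norm = config["normalize"]
        cohorts = list(fixture.annotation["cohort"].unique())
        standardized = []
        for cohort in cohorts:
            samples = fixture.annotation.loc[
                fixture.annotation["cohort"] == cohort, "sample_id"]
            sub = fixture.expression.data[list(samples)]
            from .containers import ExpressionMatrix
            em = ExpressionMatrix(sub, scale="counts")
            chained = normalize_rnaseq(em, pseudocount=norm["pseudocount"],
                                       log2_first=norm["log2_first"])
            standardized.append(zscore_within_dataset(chained))
        if len(standardized) >= 2:
            pooled = pool_datasets(standardized, cohorts)
            pooled_samples = [c.split(":", 1)[1] for c in pooled.samples]
        else:
            pooled = standardized[0]
            pooled_samples = list(pooled.samples)
        pooled_path = outdir / "pooled_expression.tsv"
        dio.write_expression(pooled, pooled_path)
        record("normalize", {"pooled_expression": pooled_path})

        # 3. differential expression over the configured grouping
        de_cfg = config["diffexpr"]
        groups = annotation.loc[pooled_samples, de_cfg["group_column"]]
        groups.index = pooled.samples
        stats = differential_expression(pooled, groups)
        selected = select_genes(stats, de_cfg["p_threshold"], de_cfg["fc_threshold"])
        de_path = outdir / "differential_expression.tsv"
        dio.write_gene_list(stats, de_path)
        genes_path = outdir / "selected_genes.tsv"
        pd.Series(selected, name="gene_id").to_csv(genes_path, sep="\t", index=False)
        record("diffexpr", {"stats": de_path, "selected_genes": genes_path})

        # 4. clustering on the selected genes
        k = config["cluster"]["k"]
        gene_list = selected if selected else list(pooled.genes)
        clusterer = CentroidLinkageClustering(n_clusters=k)
        labels = clusterer.fit_predict(pooled.data.loc[gene_list].T.to_numpy())
        assignment = assignment_table(pooled_samples, labels)
        cluster_path = outdir / "cluster_assignment.tsv"
        assignment.to_csv(cluster_path, sep="\t", index=False)
        linkage_path = outdir / "linkage.tsv"
        pd.DataFrame(clusterer.linkage_,
                     columns=["left", "right", "height", "size"]) \
            .to_csv(linkage_path, sep="\t", index=False)
        record("cluster", {"assignment": cluster_path, "linkage": linkage_path})
        truth_cluster = annotation.loc[pooled_samples, "cluster"]
        manifest["metrics"]["cluster_ari"] = float(
            adjusted_rand_score(truth_cluster, assignment["cluster"]))

        # 5. subtype classification
        bc = config["bccp"]
        X = pooled.data.T
        X.index = pooled_samples
        y = annotation.loc[pooled_samples, "subtype"]
        predictor = SubtypePredictor(alpha=bc["alpha"], top_n=bc["top_n"],
                                     node_order=tuple(bc["node_order"]),
                                     threshold=bc["threshold"])
        predictor.fit(X, y)
        calls = predictor.predict_calls(X)
        calls_path = outdir / "subtype_calls.tsv"
        calls.to_csv(calls_path, sep="\t", index_label="sample_id")
        model_path = outdir / "subtype_model.tsv"
        dio.write_model(predictor, model_path)
        record("subtype", {"calls": calls_path, "model": model_path})
        evaluation = confusion_and_rates(y.to_numpy(), calls["label"].to_numpy(),
                                         subtypes=sorted(y.unique()))
        manifest["metrics"]["subtype_accuracy"] = evaluation["accuracy"]
        if bc["cv"] == "loocv":
            cv = loocv(X, y, alpha=bc["alpha"], top_n=bc["top_n"],
                       node_order=tuple(bc["node_order"]), threshold=bc["threshold"])
            manifest["metrics"]["subtype_loocv_accuracy"] = cv["accuracy"]

        # 6. mutation statistics by cluster
        ms = config["mutstats"]
        cluster_groups = assignment.set_index("sample_id")["cluster"] \
            .reindex(fixture.mutations.samples)
        freq = mutation_frequency_table(fixture.mutations, cluster_groups)
        freq_path = outdir / "mutation_frequencies.tsv"
        freq.to_csv(freq_path, sep="\t", index=False)
        chisq_rows = []
        levels = sorted(cluster_groups.unique())
        if len(levels) == 2:
            for gene in ms["driver_genes"]:
                if gene not in fixture.mutations.indicator.index:
                    continue
                counts = {}
                for level in levels:
                    members = cluster_groups.index[cluster_groups == level]
                    mutated = int(fixture.mutations.indicator.loc[gene, members].sum())
                    counts[level] = (mutated, len(members) - mutated)
                try:
                    result = chi_square_2x2(*counts[levels[0]], *counts[levels[1]],
                                            correction=ms["yates"])
                    chisq_rows.append({"gene": gene, "chi2": result.chi2,
                                       "p_value": result.p_value})
                except ValidationError:
                    log.warning("chi-square undefined for %s (zero marginal)", gene)
        chisq_path = outdir / "driver_chisq.tsv"
        pd.DataFrame(chisq_rows, columns=["gene", "chi2", "p_value"]) \
            .to_csv(chisq_path, sep="\t", index=False)
        burdens = mutation_burden(fixture.mutations)
        burden_rows = []
        if len(levels) == 2:
            for method in ("mann_whitney", "binned_chisq"):
                try:
                    res = compare_burden(burdens, cluster_groups, method=method,
                                         breakpoints=tuple(ms["breakpoints"]))
                    burden_rows.append({"method": method, "p_value": res["p_value"]})
                except ValidationError as exc:
                    log.warning("burden comparison %s failed: %s", method, exc)
        burden_path = outdir / "burden_comparison.tsv"
        pd.DataFrame(burden_rows, columns=["method", "p_value"]) \
            .to_csv(burden_path, sep="\t", index=False)
        record("mutstats", {"frequencies": freq_path, "driver_chisq": chisq_path,
                            "burden_comparison": burden_path})

        # 7. responder report per cluster
        rp = config["responders"]
        driver = rp["driver_gene"]
        groups_spec: dict[str, dict] = {}
        subtype_by_sample = annotation.loc[pooled_samples, "subtype"]
        for level in levels:
            members = cluster_groups.index[cluster_groups == level]
            spec: dict = {"subtype_fractions":
                          subtype_fractions_from_labels(subtype_by_sample.loc[members])}
            if driver in fixture.mutations.indicator.index:
                spec["driver_mutation_fraction"] = float(
                    fixture.mutations.indicator.loc[driver, members].mean())
            groups_spec[f"cluster_{level}"] = spec
        report, notes = summarize_groups(groups_spec, rates=rp["rates"],
                                         pathway_response_rate=rp["pathway_response_rate"])
        responders_path = outdir / "responder_report.tsv"
        report.to_csv(responders_path, sep="\t", index=False)
        record("responders", {"report": responders_path})
        manifest["notes"] = notes

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
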
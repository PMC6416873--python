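"""Synthetic multi-cohort generator for expression and mutation profiles.

The generator emulates the statistical structure the downstream analysis
assumes about pooled bulk RNA-seq cohorts of gastric cancer:

* four molecular subtypes (EBV, MSI, GS, CIN), each with a disjoint block
  of up-shifted signature genes;
* negative-binomial counts on exponentiated per-gene log2 baselines, with
  per-cohort, per-gene additive batch shifts on the log2 scale and
  uniformly drawn library sizes;
* subtype-dependent total mutation burden (Poisson, high in MSI/EBV-like
  tumors and low in GS/CIN-like tumors) and driver genes with
  group-dependent Bernoulli mutation frequencies.

Randomness is driven by a single seed through a hierarchical stream
(one spawned substream per cohort plus dedicated gene-level and mutation
streams), so appending a cohort to the configuration leaves the samples of
existing cohorts byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (SUBTYPES, CohortFixture, ExpressionMatrix,
                         MutationMatrix, ValidationError)

# Mutation burden per Mb by subtype: microsatellite-unstable tumors are
# hypermutated, EBV intermediate, genomically/chromosomally stable low.
DEFAULT_BURDEN_PER_MB: dict[str, float] = {"MSI": 40.0, "EBV": 10.0, "GS": 5.0, "CIN": 5.0}

# Driver mutation frequencies by subtype: PIK3CA/ARID1A enriched in MSI and
# EBV tumors, CDH1 in genomically stable tumors, TP53 in chromosomally
# unstable tumors.
DEFAULT_DRIVER_FREQS: dict[str, dict[str, float]] = {
    "PIK3CA": {"MSI": 0.35, "EBV": 0.35, "GS": 0.05, "CIN": 0.05},
    "CDH1": {"MSI": 0.05, "EBV": 0.05, "GS": 0.30, "CIN": 0.03},
    "ARID1A": {"MSI": 0.45, "EBV": 0.35, "GS": 0.10, "CIN": 0.10},
    "TP53": {"MSI": 0.30, "EBV": 0.10, "GS": 0.15, "CIN": 0.60},
}

# Tumors of the genomically stable and EBV subtypes fall in cluster I of the
# two-cluster expression split; MSI and CIN tumors fall in cluster II.
CLUSTER_OF_SUBTYPE: dict[str, str] = {"GS": "I", "EBV": "I", "MSI": "II", "CIN": "II"}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-cohort study.

    Defaults reflect the study conditions exercised by the recovery tests:
    2,000 genes with 200 signature genes per subtype, a 2.0 log2-fold
    signature effect, 30 samples per subtype in a single cohort, and a
    ~1 Mb targeted mutation panel.
    """

    n_genes: int = 2000
    cohorts: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {"cohortA": {s: 30 for s in SUBTYPES}})
    n_signature_genes_per_subtype: int = 200
    signature_log2_effect: float = 2.0
    baseline_log2_mean_sd: tuple[float, float] = (5.0, 2.0)
    dispersion: float = 0.1
    batch_log2_sd: float = 0.5
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    burden_mean_per_mb: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BURDEN_PER_MB))
    target_region_mb: float = 1.0
    driver_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_DRIVER_FREQS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_signature_genes_per_subtype < 1:
            raise ValidationError("n_genes and n_signature_genes_per_subtype must be >= 1")
        if self.n_signature_genes_per_subtype * len(SUBTYPES) > self.n_genes:
            raise ValidationError("signature gene blocks exceed the gene universe")
        if self.signature_log2_effect < 0 or self.batch_log2_sd < 0:
            raise ValidationError("effect and batch scales must be >= 0")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.target_region_mb <= 0:
            raise ValidationError("target_region_mb must be > 0")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValidationError("library_size_range must be positive and ordered")
        total = sum(n for spec in self.cohorts.values() for n in spec.values())
        if total == 0:
            raise ValidationError("configuration has zero samples in every subtype")
        for cohort, spec in self.cohorts.items():
            unknown = set(spec) - set(SUBTYPES)
            if unknown:
                raise ValidationError(f"unknown subtypes {sorted(unknown)} in cohort {cohort}")
            if any(n < 0 for n in spec.values()):
                raise ValidationError(f"negative sample count in cohort {cohort}")
        for subtype, mean in self.burden_mean_per_mb.items():
            if mean <= 0:
                raise ValidationError(f"burden mean for {subtype} must be > 0")
        for gene, freqs in self.driver_freqs.items():
            for group, p in freqs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"driver frequency {gene}/{group} outside [0,1]")


def gene_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def signature_gene_map(config: SimulationConfig) -> dict[str, list[str]]:
    """Disjoint signature blocks: the first 4*k genes, one block per subtype."""
    ids = gene_ids(config)
    k = config.n_signature_genes_per_subtype
    return {s: ids[i * k:(i + 1) * k] for i, s in enumerate(SUBTYPES)}


def _streams(config: SimulationConfig) -> tuple[np.random.Generator, np.random.Generator,
                                                list[np.random.Generator]]:
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 + len(config.cohorts))
    gene_rng = np.random.default_rng(children[0])
    mut_rng = np.random.default_rng(children[1])
    cohort_rngs = [np.random.default_rng(c) for c in children[2:]]
    return gene_rng, mut_rng, cohort_rngs


def simulate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw counts, annotation, and ground-truth labels for all cohorts.

    Returns ``(expression, annotation, truth)`` where expression is on the
    ``counts`` scale and truth carries the planted subtype and cluster of
    every sample.
    """
    genes = gene_ids(config)
    sig = signature_gene_map(config)
    sig_rows = {s: np.asarray([genes.index(g) for g in ids]) for s, ids in sig.items()}

    gene_rng, _, cohort_rngs = _streams(config)
    mu0, sd0 = config.baseline_log2_mean_sd
    baseline = gene_rng.normal(mu0, sd0, size=config.n_genes)

    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    rows: list[dict[str, str]] = []
    r = 1.0 / config.dispersion
    for rng, (cohort, spec) in zip(cohort_rngs, config.cohorts.items()):
        batch = rng.normal(0.0, config.batch_log2_sd, size=config.n_genes) \
            if config.batch_log2_sd > 0 else np.zeros(config.n_genes)
        for subtype in SUBTYPES:
            n = int(spec.get(subtype, 0))
            if n == 0:
                continue
            log2_expr = baseline + batch
            log2_expr = log2_expr.copy()
            log2_expr[sig_rows[subtype]] += config.signature_log2_effect
            rel = np.exp2(log2_expr)
            p = rel / rel.sum()
            lib = rng.integers(config.library_size_range[0],
                               config.library_size_range[1] + 1, size=n)
            mu = np.outer(p, lib)  # genes x n
            p_nb = r / (r + mu)
            counts = rng.negative_binomial(r, p_nb)
            blocks.append(counts)
            for i in range(n):
                sid = f"{cohort}_{subtype}_{i + 1:03d}"
                sample_ids.append(sid)
                rows.append({"sample_id": sid, "cohort": cohort,
                             "histology": "diffuse", "subtype": subtype,
                             "cluster": CLUSTER_OF_SUBTYPE[subtype]})

    values = np.concatenate(blocks, axis=1)
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids),
                            scale="counts")
    annotation = pd.DataFrame(rows)
    truth = annotation[["sample_id", "subtype", "cluster"]].copy()
    return expr, annotation, truth


def simulate_mutations(config: SimulationConfig, truth: pd.DataFrame) -> MutationMatrix:
    """Draw per-sample mutation totals and driver-gene indicators.

    Totals are Poisson with subtype-dependent mean ``burden * region_Mb``;
    driver indicators are Bernoulli with group-dependent frequencies, where
    a group key may name either a subtype or a cluster label.
    """
    unknown = set(truth["subtype"]) - set(SUBTYPES)
    if unknown:
        raise ValidationError(f"unknown subtypes in truth labels: {sorted(unknown)}")
    _, mut_rng, _ = _streams(config)
    samples = list(truth["sample_id"])
    subtype = truth.set_index("sample_id")["subtype"]
    cluster = truth.set_index("sample_id")["cluster"] if "cluster" in truth else None

    means = np.array([config.burden_mean_per_mb[subtype[s]] * config.target_region_mb
                      for s in samples])
    totals = mut_rng.poisson(means)

    driver_genes = sorted(config.driver_freqs)
    indicator = np.zeros((len(driver_genes), len(samples)), dtype=int)
    for gi, gene in enumerate(driver_genes):
        freqs = config.driver_freqs[gene]
        for si, s in enumerate(samples):
            p = freqs.get(subtype[s])
            if p is None and cluster is not None:
                p = freqs.get(cluster[s])
            p = 0.0 if p is None else p
            indicator[gi, si] = int(mut_rng.random() < p)

    totals = np.maximum(totals, indicator.sum(axis=0))
    return MutationMatrix(
        indicator=pd.DataFrame(indicator, index=driver_genes, columns=samples),
        total_mutations=pd.Series(totals, index=samples, name="total_mutations"),
        target_region_mb=config.target_region_mb,
    )


def simulate_cohorts(config: SimulationConfig) -> CohortFixture:
    """Full fixture: expression + annotation + mutations + truth labels."""
    expr, annotation, truth = simulate_expression(config)
    mutations = simulate_mutations(config, truth)
    return CohortFixture(expression=expr, annotation=annotation,
                         mutations=mutations, truth=truth,
                         signature_genes=signature_gene_map(config))


def write_fixture(fixture: CohortFixture, directory: str | Path) -> dict[str, Path]:
    """Write a fixture as tab-separated tables (one expression file per cohort).

    Round-trips losslessly through :mod:`diffgc.io` readers.
    """
    from . import io as dio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cohort, group in fixture.annotation.groupby("cohort", sort=False):
        sub = ExpressionMatrix(fixture.expression.data[group["sample_id"]],
                               scale=fixture.expression.scale)
        path = directory / f"expression_{cohort}.tsv"
        dio.write_expression(sub, path)
        paths[f"expression_{cohort}"] = path
    paths["annotation"] = directory / "annotation.tsv"
    fixture.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    paths["truth"] = directory / "truth.tsv"
    fixture.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["mutations"] = directory / "mutations.tsv"
    dio.write_maf(fixture.mutations, paths["mutations"])
    paths["mutation_totals"] = directory / "mutation_totals.tsv"
    dio.write_mutation_totals(fixture.mutations, paths["mutation_totals"])
    return paths
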
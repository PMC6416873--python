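"""Readers and writers for the tab-separated interchange formats.

Expression matrices are TSV with one header row of sample IDs, a first
column of gene IDs, and a leading ``# scale=<tag>`` metadata line.
Mutations travel either as a MAF-like long table (sample_id, gene,
variant_class) plus a totals table, or pre-collapsed as a binary matrix.
All readers raise explicit errors naming the offending ID or cell.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MutationMatrix, ValidationError


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="gene_id")


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("# scale="):
            scale = first.split("=", 1)[1]
            header = fh.readline().rstrip("\n").split("\t")
        else:
            scale = "counts"
            header = first.split("\t")
        samples = header[1:]
        seen: set[str] = set()
        for sid in samples:  # pandas would silently mangle duplicate columns
            if sid in seen:
                raise ValidationError(f"duplicate sample ID {sid!r} in {path}")
            seen.add(sid)
        frame = pd.read_csv(fh, sep="\t", header=None, index_col=0)
        frame.columns = samples
        frame.index.name = None
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"duplicate gene ID {dup!r} in {path}")
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            gene = frame.index[bad][0]
            raise ValidationError(
                f"non-numeric value at gene {gene!r}, sample {col!r} in {path}")
        frame[col] = converted
    if frame.isna().any().any():
        loc = np.argwhere(frame.isna().to_numpy())[0]
        raise ValidationError(
            f"missing value at gene {frame.index[loc[0]]!r}, "
            f"sample {frame.columns[loc[1]]!r} in {path}")
    return ExpressionMatrix(frame, scale=scale)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in frame.columns:
        raise ValidationError(f"annotation {path} lacks a sample_id column")
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample ID {dup!r} in {path}")
    return frame


def write_maf(mut: MutationMatrix, path: str | Path) -> None:
    """Binary matrix -> MAF-like long table (sample_id, gene, variant_class)."""
    rows = []
    for gene in mut.indicator.index:
        for sample in mut.indicator.columns:
            if mut.indicator.at[gene, sample]:
                rows.append({"sample_id": sample, "gene": gene,
                             "variant_class": "Missense_Mutation"})
    pd.DataFrame(rows, columns=["sample_id", "gene", "variant_class"]) \
        .to_csv(path, sep="\t", index=False)


def write_mutation_totals(mut: MutationMatrix, path: str | Path) -> None:
    frame = mut.total_mutations.rename("total_mutations").to_frame()
    frame["target_region_mb"] = mut.target_region_mb
    frame.to_csv(path, sep="\t", index_label="sample_id")


def read_maf(maf_path: str | Path, totals_path: str | Path,
             samples: list[str] | None = None) -> MutationMatrix:
    """MAF-like table + totals table -> binary MutationMatrix.

    ``samples`` fixes the sample universe and order (samples with no
    mutations would otherwise be invisible in the long table); defaults to
    the totals table's order.
    """
    maf = pd.read_csv(maf_path, sep="\t", dtype=str)
    for col in ("sample_id", "gene"):
        if col not in maf.columns:
            raise ValidationError(f"MAF {maf_path} lacks a {col} column")
    totals = pd.read_csv(totals_path, sep="\t", index_col="sample_id")
    if samples is None:
        samples = list(totals.index)
    genes = sorted(maf["gene"].unique()) if len(maf) else []
    indicator = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for _, row in maf.iterrows():
        if row["sample_id"] not in indicator.columns:
            raise ValidationError(
                f"MAF sample {row['sample_id']!r} missing from totals table")
        indicator.at[row["gene"], row["sample_id"]] = 1
    region = float(totals["target_region_mb"].iloc[0]) if len(totals) else 1.0
    return MutationMatrix(indicator=indicator,
                          total_mutations=totals["total_mutations"]
                          .astype(int).reindex(samples),
                          target_region_mb=region)


def write_gene_list(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index_label=stats.index.name or "gene_id")


def write_model(model, path: str | Path) -> None:
    """Serialize a fitted SubtypePredictor as plain text.

    A parameter block (key<TAB>value lines starting with '#') followed by a
    (subtype, gene, weight) table.
    """
    lines = [f"#param\talpha\t{model.alpha}",
             f"#param\ttop_n\t{model.top_n}",
             f"#param\tnode_order\t{','.join(model.node_order)}",
             f"#param\tthreshold\t{model.threshold}",
             f"#param\tpriors\t{model.priors[0]},{model.priors[1]}"]
    for s, m in model.models_.items():
        if m is None:
            continue
        lines.append(f"#class\t{s}\t{m.mu_pos_}\t{m.mu_neg_}\t{m.sigma_}")
    lines.append("subtype\tgene\tweight")
    for s, m in model.models_.items():
        if m is None:
            continue
        for gene, w in zip(model.panels_[s].genes, m.weights_):
            lines.append(f"{s}\t{gene}\t{w!r}")
    Path(path).write_text("\n".join(lines) + "\n")
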
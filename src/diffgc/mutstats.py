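"""Mutation-profile statistics.

Group-wise mutation-frequency tables, 2x2 Pearson chi-square tests
(no continuity correction by default — the convention that reproduces the
printed cohort P-values), mutations/Mb burden computation and group
comparison, and the MSI-high calling rule (> 30% of assayed microsatellite
markers unstable, strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import MutationMatrix, ValidationError


@dataclass
class ContingencyResult:
    table: np.ndarray  # 2x2 [[a, b], [c, d]]
    chi2: float
    df: int
    p_value: float
    correction: str  # "none" | "yates"


def mutation_frequency_table(mut: MutationMatrix, groups: pd.Series | dict,
                             top_n: int = 15) -> pd.DataFrame:
    """Per-group mutation frequencies of the top ``top_n`` most mutated genes.

    Genes are ranked by overall mutation count (ties by gene ID); genes
    mutated in no sample are excluded. Each group column reports
    ``mutated/total`` counts and the percentage to one decimal.
    """
    groups = pd.Series(groups).reindex(mut.samples)
    if groups.isna().any():
        raise ValidationError("group labels missing for some samples")
    if (groups.value_counts() == 0).any():
        raise ValidationError("empty group")
    overall = mut.indicator.sum(axis=1)
    ranked = sorted(overall.index[overall > 0],
                    key=lambda g: (-overall[g], str(g)))[:top_n]
    rows = []
    for gene in ranked:
        row: dict[str, object] = {"gene": gene, "overall_count": int(overall[gene])}
        for level in sorted(groups.unique()):
            members = groups.index[groups == level]
            mutated = int(mut.indicator.loc[gene, members].sum())
            total = len(members)
            row[f"{level}_count"] = f"{mutated}/{total}"
            row[f"{level}_percent"] = round(100.0 * mutated / total, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def chi_square_2x2(a: int, b: int, c: int, d: int,
                   correction: bool = False) -> ContingencyResult:
    """Pearson chi-square on the table [[a, b], [c, d]] with df = 1.

    ``a/b`` are mutated/unmutated counts in group A, ``c/d`` in group B.
    Continuity (Yates) correction is off by default.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValidationError("counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n < 1:
        raise ValidationError("empty table")
    marginals = (a + b, c + d, a + c, b + d)
    if 0 in marginals:
        raise ValidationError("zero marginal row or column: test undefined")
    diff = abs(a * d - b * c)
    if correction:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff ** 2 / np.prod([float(m) for m in marginals])
    p = float(sps.chi2.sf(chi2, df=1))
    return ContingencyResult(table=np.array([[a, b], [c, d]]), chi2=float(chi2),
                             df=1, p_value=p,
                             correction="yates" if correction else "none")


def mutation_burden(mut: MutationMatrix) -> pd.Series:
    """Per-sample mutations per megabase of targeted coding territory."""
    return (mut.total_mutations / mut.target_region_mb).rename("mutations_per_mb")


def compare_burden(burdens: pd.Series, groups: pd.Series | dict,
                   method: str = "mann_whitney",
                   breakpoints: tuple[float, ...] = (100.0, 500.0)) -> dict:
    """Compare mutation burden between two groups.

    ``mann_whitney``: two-sided rank-sum test (tie-corrected).
    ``binned_chisq``: samples binned by mutation-count breakpoints
    (default bins 0-100, 101-500, >500), r x 2 Pearson chi-square on the
    bin-count table; an expected count of zero is an error.
    """
    burdens = pd.Series(burdens)
    groups = pd.Series(groups).reindex(burdens.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValidationError(f"expected two groups, got {levels}")
    x = burdens[groups == levels[0]].to_numpy()
    y = burdens[groups == levels[1]].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("a group is empty")
    if method == "mann_whitney":
        if np.array_equal(np.sort(x), np.sort(y)):
            return {"method": method, "p_value": 1.0, "statistic": float(len(x) * len(y) / 2)}
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        return {"method": method, "p_value": float(p), "statistic": float(stat)}
    if method == "binned_chisq":
        edges = [-np.inf, *breakpoints, np.inf]
        counts = np.array([np.histogram(v, bins=edges)[0] for v in (x, y)]).T  # r x 2
        keep = counts.sum(axis=1) > 0
        counts = counts[keep]
        if counts.shape[0] < 2:
            raise ValidationError("fewer than two occupied bins")
        expected = sps.contingency.expected_freq(counts)
        if (expected == 0).any():
            raise ValidationError("zero expected count in binned chi-square")
        chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
        return {"method": method, "p_value": float(p), "statistic": float(chi2),
                "df": int(dof), "bins": counts}
    raise ValidationError(f"unknown method {method!r}")


def msi_call(unstable_markers: int, total_markers: int) -> str:
    """MSI-H iff strictly more than 30% of assayed markers are unstable."""
    if total_markers < 1:
        raise ValidationError("total_markers must be >= 1")
    if not 0 <= unstable_markers <= total_markers:
        raise ValidationError("unstable_markers outside [0, total_markers]")
    # strict > 0.30, compared in integers to dodge float boundary artifacts
    return "MSI-H" if unstable_markers * 10 > total_markers * 3 else "non-MSI-H"
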
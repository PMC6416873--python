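"""Treatment-responder estimation arithmetic.

Two estimators:

* checkpoint inhibitors — expected responder fraction of a patient group is
  the subtype composition dotted with per-subtype response rates. Default
  rates follow reported trial results of PD-1 blockade in metastatic
  gastric cancer: responses in all MSI and EBV cases, 5% of CIN and 12% of
  GS cases.
* mTOR-pathway inhibitors — expected responder fraction is the group's
  driver (PIK3CA) mutation frequency times the reported 35% response rate
  of PIK3CA-mutant tumors to PI3K/AKT/mTOR pathway inhibitors.

Percentages are rounded half-away-from-zero; unrounded fractions and full
provenance (the terms multiplied) are always carried alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .containers import SUBTYPES, ValidationError

DEFAULT_RESPONSE_RATES: dict[str, float] = {"MSI": 1.0, "EBV": 1.0, "CIN": 0.05, "GS": 0.12}
DEFAULT_PATHWAY_RESPONSE_RATE = 0.35


def round_percent(fraction: float) -> int:
    """Integer percent, half-away-from-zero (0.0907 -> 9, 0.0385 -> 4)."""
    scaled = fraction * 100.0
    return int(math.copysign(math.floor(abs(scaled) + 0.5), scaled))


@dataclass
class ResponderEstimate:
    group: str
    therapy: str
    estimated_fraction: float
    rounded_percent: int
    provenance: dict = field(default_factory=dict)


def subtype_fractions_from_labels(subtypes: pd.Series | list) -> dict[str, float]:
    """Counts -> fractions over the four subtypes (absent subtypes get 0)."""
    counts = pd.Series(subtypes).value_counts()
    total = int(counts.sum())
    if total == 0:
        raise ValidationError("no samples")
    return {s: float(counts.get(s, 0)) / total for s in SUBTYPES}


def checkpoint_responder_rate(subtype_fractions: Mapping[str, float],
                              rates: Mapping[str, float] | None = None,
                              group: str = "group") -> ResponderEstimate:
    """Expected checkpoint-inhibitor responder fraction: sum_s f_s * rho_s."""
    rates = dict(DEFAULT_RESPONSE_RATES if rates is None else rates)
    missing = set(SUBTYPES) - set(rates)
    if missing:
        raise ValidationError(f"response rates missing for {sorted(missing)}")
    for s, rho in rates.items():
        if not 0.0 <= rho <= 1.0:
            raise ValidationError(f"rate for {s} outside [0,1]")
    fractions = {s: float(subtype_fractions.get(s, 0.0)) for s in SUBTYPES}
    if any(f < 0 for f in fractions.values()):
        raise ValidationError("negative subtype fraction")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValidationError("subtype fractions must sum to 1")
    terms = {s: fractions[s] * rates[s] for s in SUBTYPES}
    fraction = sum(terms.values())
    return ResponderEstimate(
        group=group, therapy="checkpoint_inhibitor",
        estimated_fraction=fraction, rounded_percent=round_percent(fraction),
        provenance={"subtype_fractions": fractions, "response_rates": rates,
                    "terms": terms})


def mtor_responder_rate(driver_mutation_fraction: float,
                        pathway_response_rate: float = DEFAULT_PATHWAY_RESPONSE_RATE,
                        group: str = "group") -> ResponderEstimate:
    """Expected mTOR-inhibitor responder fraction:
    driver mutation frequency x pathway response rate."""
    for name, v in (("driver_mutation_fraction", driver_mutation_fraction),
                    ("pathway_response_rate", pathway_response_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} outside [0,1]")
    fraction = driver_mutation_fraction * pathway_response_rate
    return ResponderEstimate(
        group=group, therapy="mtor_inhibitor",
        estimated_fraction=fraction, rounded_percent=round_percent(fraction),
        provenance={"driver_mutation_fraction": driver_mutation_fraction,
                    "pathway_response_rate": pathway_response_rate})


def summarize_groups(groups: Mapping[str, Mapping],
                     rates: Mapping[str, float] | None = None,
                     pathway_response_rate: float = DEFAULT_PATHWAY_RESPONSE_RATE
                     ) -> tuple[pd.DataFrame, list[str]]:
    """One row per group and therapy.

    ``groups`` maps a group label to a dict with optional keys
    ``subtype_fractions`` (for the checkpoint estimate) and
    ``driver_mutation_fraction`` (for the mTOR estimate); an optional
    ``drivers_in_responder_subtypes`` flag marks groups whose driver-mutant
    tumors all fall in MSI/EBV subtypes, in which case the mTOR responders
    are a subset of the checkpoint responders and a containment note is
    emitted.
    """
    rows, notes = [], []
    for group, spec in groups.items():
        estimates: list[ResponderEstimate] = []
        if "subtype_fractions" in spec:
            estimates.append(checkpoint_responder_rate(
                spec["subtype_fractions"], rates, group=group))
        if "driver_mutation_fraction" in spec:
            estimates.append(mtor_responder_rate(
                spec["driver_mutation_fraction"], pathway_response_rate, group=group))
        for est in estimates:
            rows.append({"group": est.group, "therapy": est.therapy,
                         "estimated_fraction": est.estimated_fraction,
                         "rounded_percent": est.rounded_percent,
                         "provenance": est.provenance})
        if spec.get("drivers_in_responder_subtypes") and len(estimates) == 2:
            notes.append(
                f"{group}: all driver-mutant tumors are MSI/EBV, so estimated "
                "mTOR-inhibitor responders are a subset of checkpoint-inhibitor "
                "responders")
    return pd.DataFrame(rows), notes
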
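"""Dose-response classification of promoter DHS / gene pairs.

A promoter-overlapping DHS is assigned to one of three Notch dose-response
classes (or left unclassified) by combining three strands of evidence:
per-stage accessibility calls, the adjusted differential-accessibility
p-values of the LSK-vs-DN1 and DN1-vs-DN2b comparisons, and the expression
gates on stage-pair log2 fold-changes.

low_I   accessibility acquired de novo at the LSK -> DN1 transition:
        LSK inaccessible, DN1 accessible, significant LSK-vs-DN1 change,
        low expression gate.
low_II  accessible already in LSK but significantly increased in DN1
        (positive DN1 - LSK effect), low expression gate.
high    inaccessible in LSK and DN1, accessible de novo in DN2b,
        significant DN1-vs-DN2b change, high expression gate.

Predicates are evaluated in the order high -> low_I -> low_II; a gene-region
pair receives exactly one class.  DN2a evidence is carried but not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DOSE_CLASSES = ("low_I", "low_II", "high")
REQUIRED_STAGES = ("LSK", "DN1", "DN2b")
REQUIRED_PAIRS = (("LSK", "DN1"), ("DN1", "DN2b"))


@dataclass
class DoseClassification:
    """Class assignment of one gene-region pair with its evidence."""

    gene_id: str
    region_id: str
    dose_class: str  # low_I | low_II | high | unclassified
    evidence: dict = field(default_factory=dict)


def classify_promoter(
    gene_id: str,
    region_id: str,
    accessible: Mapping[str, bool],
    p_adjusted: Mapping[tuple[str, str], float],
    delta_mean_rpm: Mapping[tuple[str, str], float],
    gates: Mapping[str, bool],
    alpha: float = 0.05,
) -> DoseClassification:
    """Apply the dose-response criteria to one gene-region pair.

    ``accessible`` maps stage -> call; ``p_adjusted`` and ``delta_mean_rpm``
    map the (LSK, DN1) and (DN1, DN2b) pairs to the adjusted p and the
    signed effect (mean RPM of the first stage minus the second); ``gates``
    holds the ``low`` and ``high`` expression gate booleans.
    """
    for stage in REQUIRED_STAGES:
        if stage not in accessible:
            raise KeyError(f"{gene_id}/{region_id}: missing accessibility call for {stage}")
    for pair in REQUIRED_PAIRS:
        if pair not in p_adjusted or pair not in delta_mean_rpm:
            raise KeyError(f"{gene_id}/{region_id}: missing differential result for {pair}")
    for gate in ("low", "high"):
        if gate not in gates:
            raise KeyError(f"{gene_id}/{region_id}: missing {gate} expression gate")

    sig_lsk_dn1 = p_adjusted[("LSK", "DN1")] < alpha
    sig_dn1_dn2b = p_adjusted[("DN1", "DN2b")] < alpha
    dn1_gain = delta_mean_rpm[("LSK", "DN1")] < 0  # DN1 above LSK

    if (
        not accessible["LSK"]
        and not accessible["DN1"]
        and accessible["DN2b"]
        and sig_dn1_dn2b
        and gates["high"]
    ):
        dose_class = "high"
    elif (
        not accessible["LSK"]
        and accessible["DN1"]
        and sig_lsk_dn1
        and gates["low"]
    ):
        dose_class = "low_I"
    elif (
        accessible["LSK"]
        and accessible["DN1"]
        and sig_lsk_dn1
        and dn1_gain
        and gates["low"]
    ):
        dose_class = "low_II"
    else:
        dose_class = "unclassified"

    evidence = {
        "accessible": dict(accessible),
        "p_adjusted": {f"{a}_vs_{b}": p for (a, b), p in p_adjusted.items()},
        "delta_mean_rpm": {f"{a}_vs_{b}": d for (a, b), d in delta_mean_rpm.items()},
        "gates": dict(gates),
        "alpha": alpha,
    }
    return DoseClassification(gene_id, region_id, dose_class, evidence)


def classify_table(
    assignments: Sequence[tuple[str, str]],
    calls: pd.DataFrame,
    diffs: pd.DataFrame,
    gates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every (dhs_id, gene_id) assignment.

    ``calls`` is the output of :func:`notchdose.diffaccess.call_accessibility`;
    ``diffs`` the adjusted differential table covering the (LSK, DN1) and
    (DN1, DN2b) pairs; ``gates`` a gene-indexed frame with ``low``/``high``
    columns.  Genes absent from ``gates`` (e.g. removed by the CPM filter)
    fail both gates.
    """
    acc = calls.pivot(index="region_id", columns="stage", values="accessible")
    padj = diffs.pivot(index="region_id", columns=["stage_a", "stage_b"], values="p_adjusted")
    delta = diffs.pivot(index="region_id", columns=["stage_a", "stage_b"], values="delta_mean_rpm")

    rows = []
    for region_id, gene_id in assignments:
        if region_id not in acc.index:
            raise KeyError(f"no accessibility calls for region {region_id!r}")
        if region_id not in padj.index:
            raise KeyError(f"no differential results for region {region_id!r}")
        if gene_id in gates.index:
            gene_gates = {"low": bool(gates.loc[gene_id, "low"]),
                          "high": bool(gates.loc[gene_id, "high"])}
        else:
            gene_gates = {"low": False, "high": False}
        result = classify_promoter(
            gene_id,
            region_id,
            accessible=acc.loc[region_id].to_dict(),
            p_adjusted={p: float(padj.loc[region_id, p]) for p in REQUIRED_PAIRS},
            delta_mean_rpm={p: float(delta.loc[region_id, p]) for p in REQUIRED_PAIRS},
            gates=gene_gates,
            alpha=alpha,
        )
        rows.append(
            {
                "gene_id": gene_id,
                "region_id": region_id,
                "dose_class": result.dose_class,
                "accessible_LSK": result.evidence["accessible"]["LSK"],
                "accessible_DN1": result.evidence["accessible"]["DN1"],
                "accessible_DN2b": result.evidence["accessible"]["DN2b"],
                "p_adj_LSK_vs_DN1": result.evidence["p_adjusted"]["LSK_vs_DN1"],
                "p_adj_DN1_vs_DN2b": result.evidence["p_adjusted"]["DN1_vs_DN2b"],
                "delta_LSK_vs_DN1": result.evidence["delta_mean_rpm"]["LSK_vs_DN1"],
                "delta_DN1_vs_DN2b": result.evidence["delta_mean_rpm"]["DN1_vs_DN2b"],
                "gate_low": gene_gates["low"],
                "gate_high": gene_gates["high"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "region_id", "dose_class",
            "accessible_LSK", "accessible_DN1", "accessible_DN2b",
            "p_adj_LSK_vs_DN1", "p_adj_DN1_vs_DN2b",
            "delta_LSK_vs_DN1", "delta_DN1_vs_DN2b",
            "gate_low", "gate_high",
        ],
    )


def summarize_classes(classifications: pd.DataFrame) -> dict:
    """Unique gene lists per class, pairwise overlaps, and the low-dose union.

    A gene hit by several DHS regions may appear in more than one class but
    contributes once per class list and once to the unique low-dose union.
    """
    genes: dict[str, list[str]] = {}
    for dose_class in DOSE_CLASSES:
        if len(classifications):
            members = classifications.loc[
                classifications["dose_class"] == dose_class, "gene_id"
            ]
            genes[dose_class] = sorted(set(members))
        else:
            genes[dose_class] = []
    sets = {c: set(g) for c, g in genes.items()}
    overlaps = {
        f"{a}&{b}": len(sets[a] & sets[b])
        for i, a in enumerate(DOSE_CLASSES)
        for b in DOSE_CLASSES[i + 1 :]
    }
    low_union = sets["low_I"] | sets["low_II"]
    return {
        "genes": genes,
        "class_sizes": {c: len(g) for c, g in genes.items()},
        "overlaps": overlaps,
        "n_unique_low_dose": len(low_union),
        "n_unique_high_dose": len(sets["high"]),
    }
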
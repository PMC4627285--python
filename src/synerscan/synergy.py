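"""Synergy-factor scoring and the Synergistic Target classification.

The central statistic is a Bliss-style synergy factor on linear fold
changes::

    SF = FC_combo / (FC_drug * FC_ligand)

where each fold change is relative to the matched vehicle/untreated
reference (DMSO, no ligand) within a genotype, with replicates averaged on
the log2 scale (geometric mean on the linear scale). Under multiplicative
independence of the two treatments SF = 1; SF > 1 means the combination
induces more than the product of the single treatments predicts.

A gene is a **synergistic target** when all three criteria hold strictly:

* c1 — combo induction exceeds ``fc_combo_over_single`` (default 2) times
  each single-treatment induction;
* c2 — SF exceeds ``sf_min`` (default 1.5);
* c3 — combo induction in the p53-proficient genotype exceeds
  ``genotype_dependence_fold`` (default 2) times the combo induction in
  the p53-knockdown genotype.

Targets are optionally sub-classified as inhibitor-dependent when the
kinase-inhibitor arm attenuates their combo induction more than
``attenuation_fold`` (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DRUGS, LIGANDS, ExpressionMatrix, SampleDesign

REFERENCE = ("DMSO", "none")  # (drug, ligand) vehicle/untreated cell


@dataclass
class SynergyCriteria:
    """Thresholds of the synergistic-target definition (all strict)."""

    fc_combo_over_single: float = 2.0
    sf_min: float = 1.5
    genotype_dependence_fold: float = 2.0
    min_combo_fc: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fc_combo_over_single", "sf_min", "genotype_dependence_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_combo_fc < 1.0:
            raise ValueError("min_combo_fc must be >= 1")


@dataclass
class FoldChangeTable:
    """Per-gene linear fold changes for one genotype (and inhibitor state).

    ``table`` is indexed by gene ID with columns ``fc_drug``, ``fc_ligand``
    and ``fc_combo``, each relative to the (DMSO, no-ligand) reference.
    """

    table: pd.DataFrame
    genotype: str
    inhibitor: str = "none"

    def __post_init__(self) -> None:
        required = ("fc_drug", "fc_ligand", "fc_combo")
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"fold-change table missing columns: {missing}")
        if (self.table[list(required)].to_numpy() <= 0).any():
            raise ValueError("fold changes must be strictly positive")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.table.index]


def condition_fold_changes(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    genotype: str,
    inhibitor: str = "none",
) -> FoldChangeTable:
    """Linear fold changes of each (drug, ligand) condition vs the reference.

    Replicates are averaged on the log2 scale within each condition, then
    ``FC = 2**(mean_condition - mean_reference)``. Works on matrices
    declared linear (log2 taken first) or log2.
    """
    if matrix.scale == "linear":
        log2_values = np.log2(matrix.values.to_numpy())
    else:
        log2_values = matrix.values.to_numpy()
    log2_df = pd.DataFrame(log2_values, index=matrix.values.index, columns=matrix.values.columns)

    means: dict[tuple[str, str], np.ndarray] = {}
    for drug in DRUGS:
        for ligand in LIGANDS:
            samples = design.samples_for(genotype, drug, ligand, inhibitor)
            samples = [s for s in samples if s in log2_df.columns]
            if not samples:
                raise ValueError(
                    f"missing condition cell (genotype={genotype}, drug={drug}, "
                    f"ligand={ligand}, inhibitor={inhibitor})"
                )
            means[(drug, ligand)] = log2_df[samples].to_numpy().mean(axis=1)

    ref = means[REFERENCE]
    table = pd.DataFrame(
        {
            "fc_drug": 2.0 ** (means[("Nutlin", "none")] - ref),
            "fc_ligand": 2.0 ** (means[("DMSO", "flagellin")] - ref),
            "fc_combo": 2.0 ** (means[("Nutlin", "flagellin")] - ref),
        },
        index=matrix.values.index,
    )
    table.index.name = "gene_id"
    return FoldChangeTable(table, genotype, inhibitor)


def synergy_factor(fc_combo, fc_drug, fc_ligand):
    """SF = FC_combo / (FC_drug * FC_ligand); accepts scalars or arrays."""
    fc_combo = np.asarray(fc_combo, dtype=float)
    fc_drug = np.asarray(fc_drug, dtype=float)
    fc_ligand = np.asarray(fc_ligand, dtype=float)
    if (fc_combo <= 0).any() or (fc_drug <= 0).any() or (fc_ligand <= 0).any():
        raise ValueError("fold changes must be strictly positive")
    sf = fc_combo / (fc_drug * fc_ligand)
    return float(sf) if sf.ndim == 0 else sf


def classify_synergistic(
    fc_vector: FoldChangeTable,
    fc_p53i: FoldChangeTable,
    criteria: SynergyCriteria | None = None,
) -> pd.DataFrame:
    """Apply the three-part synergistic-target definition per gene.

    Returns a table indexed by gene with the vector-genotype fold changes,
    the p53i combo fold change, SF, the per-criterion boolean flags and the
    final classification (``synergistic_target`` iff c1 & c2 & c3).
    """
    criteria = criteria or SynergyCriteria()
    genes_v = set(fc_vector.genes)
    genes_p = set(fc_p53i.genes)
    if genes_v != genes_p:
        diff = sorted(genes_v.symmetric_difference(genes_p))
        raise ValueError(f"fold-change tables cover different genes: {diff[:10]}")

    tv = fc_vector.table
    tp = fc_p53i.table.loc[tv.index]
    sf = synergy_factor(
        tv["fc_combo"].to_numpy(), tv["fc_drug"].to_numpy(), tv["fc_ligand"].to_numpy()
    )
    t = criteria.fc_combo_over_single
    c1 = (
        (tv["fc_combo"] > t * tv["fc_drug"])
        & (tv["fc_combo"] > t * tv["fc_ligand"])
        & (tv["fc_combo"] > criteria.min_combo_fc)
    )
    c2 = pd.Series(sf > criteria.sf_min, index=tv.index)
    c3 = tv["fc_combo"] > criteria.genotype_dependence_fold * tp["fc_combo"]
    is_target = c1 & c2 & c3

    result = pd.DataFrame(
        {
            "fc_drug": tv["fc_drug"],
            "fc_ligand": tv["fc_ligand"],
            "fc_combo": tv["fc_combo"],
            "fc_combo_p53i": tp["fc_combo"],
            "sf": sf,
            "c1_combo_over_singles": c1,
            "c2_synergy_factor": c2,
            "c3_genotype_dependence": c3,
            "classification": np.where(is_target, "synergistic_target", "not_synergistic"),
        },
        index=tv.index,
    )
    result.index.name = "gene_id"
    return result


def synergistic_targets(results: pd.DataFrame) -> list[str]:
    """Gene IDs classified as synergistic targets, in table order."""
    mask = results["classification"] == "synergistic_target"
    return [str(g) for g in results.index[mask]]


def classify_inhibitor_dependent(
    results: pd.DataFrame,
    fc_inhibitor: FoldChangeTable,
    fc_no_inhibitor: FoldChangeTable,
    attenuation_fold: float = 2.0,
) -> pd.DataFrame:
    """Flag synergistic targets whose combo induction the inhibitor attenuates.

    A target is inhibitor-dependent when
    ``FC_combo(no inhibitor) > attenuation_fold * FC_combo(inhibitor)``
    (strict). Non-target genes are never flagged.
    """
    if attenuation_fold <= 0:
        raise ValueError("attenuation_fold must be > 0")
    if fc_inhibitor.inhibitor == "none":
        raise ValueError("fc_inhibitor must come from an inhibitor arm")
    out = results.copy()
    genes = out.index
    missing = [g for g in genes if g not in fc_inhibitor.table.index]
    if missing:
        raise ValueError(f"inhibitor arm lacks genes: {missing[:10]}")
    with_inh = fc_inhibitor.table.loc[genes, "fc_combo"]
    without = fc_no_inhibitor.table.loc[genes, "fc_combo"]
    dependent = without > attenuation_fold * with_inh
    is_target = out["classification"] == "synergistic_target"
    out["inhibitor_dependent"] = (dependent & is_target).astype(bool)
    return out


def differential_lists(
    fc_vector: FoldChangeTable, up_fold: float = 2.0, down_fold: float = 2.0
) -> dict[str, list[str]]:
    """Simple threshold lists of drug-induced/-repressed and ligand-induced genes.

    ``drug_up`` = FC_drug > up_fold; ``drug_down`` = FC_drug < 1/down_fold;
    ``ligand_up`` = FC_ligand > up_fold. All comparisons strict; lists may
    overlap.
    """
    if up_fold <= 1 or down_fold <= 1:
        raise ValueError("up_fold and down_fold must be > 1")
    t = fc_vector.table
    return {
        "drug_up": [str(g) for g in t.index[t["fc_drug"] > up_fold]],
        "drug_down": [str(g) for g in t.index[t["fc_drug"] < 1.0 / down_fold]],
        "ligand_up": [str(g) for g in t.index[t["fc_ligand"] > up_fold]],
    }
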
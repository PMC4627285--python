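"""Synthetic factorial expression data with planted ground truth.

Emulates a 2(genotype) x 2(drug) x 2(ligand) factorial with replicates —
p53-proficient ("vector") versus p53-knockdown ("p53i") cells, an MDM2
inhibitor versus vehicle, and a TLR5 ligand versus none — plus an optional
p38-inhibitor arm in the p53-proficient genotype.

Effects are additive on the log2 scale, hence multiplicative on the linear
scale: a planted log2 interaction of 2 means the combination induces
2^2 = 4-fold more than the product of the single-treatment fold changes
predicts. Every gene carries a class label recorded in
:class:`SyntheticTruth`, which downstream recovery tests use as the oracle.

Gene classes
------------
``null``
    baseline plus noise only.
``p53_induced`` / ``p53_repressed``
    drug main effect (+/-) in the p53-proficient genotype only; the
    knockdown is treated as complete by default.
``ligand_induced``
    ligand main effect in both genotypes (the ligand response does not
    require p53).
``synergistic`` / ``synergistic_inhibitor_dependent``
    drug effect (p53-dependent), ligand effect (both genotypes), and an
    extra interaction effect in the combined condition (p53-dependent).
    For the inhibitor-dependent subclass the interaction is attenuated
    when the kinase inhibitor is present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    DRUGS,
    GENOTYPES,
    LIGANDS,
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
)

CLASSES = (
    "null",
    "p53_induced",
    "p53_repressed",
    "ligand_induced",
    "synergistic",
    "synergistic_inhibitor_dependent",
)

SYNERGISTIC_CLASSES = ("synergistic", "synergistic_inhibitor_dependent")


def _default_fractions() -> dict[str, float]:
    return {
        "null": 0.75,
        "p53_induced": 0.08,
        "p53_repressed": 0.08,
        "ligand_induced": 0.04,
        "synergistic": 0.04,
        "synergistic_inhibitor_dependent": 0.01,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic factorial experiment.

    All effect sizes and noise are in log2 units. Defaults plant 5% of genes
    as synergistic (4% inhibitor-independent + 1% inhibitor-dependent) with
    log2 main effects of 1 (2-fold), a log2 interaction of 2 (4-fold extra
    induction in the combination), and i.i.d. Gaussian noise of 0.25.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    class_fractions: dict[str, float] = field(default_factory=_default_fractions)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    effect_drug: float = 1.0
    effect_ligand: float = 1.0
    effect_interaction: float = 2.0
    inhibitor_attenuation: float = 2.0
    p53_knockdown_efficiency: float = 1.0  # 1.0 = complete knockdown
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown gene class(es): {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class_fractions must be non-negative")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.p53_knockdown_efficiency <= 1.0:
            raise ValueError("p53_knockdown_efficiency must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted per-gene class labels and realized log2 effects.

    ``table`` is indexed by gene ID with columns ``gene_class``,
    ``effect_drug``, ``effect_ligand``, ``effect_interaction`` (the effects
    realized in the p53-proficient genotype; zero for factors the class does
    not use) and boolean ``inhibitor_dependent``.
    """

    table: pd.DataFrame

    def genes_in_class(self, label: str) -> list[str]:
        if label not in CLASSES:
            raise ValueError(f"unknown gene class {label!r}")
        return [str(g) for g in self.table.index[self.table["gene_class"] == label]]

    @property
    def synergistic_genes(self) -> list[str]:
        mask = self.table["gene_class"].isin(SYNERGISTIC_CLASSES)
        return [str(g) for g in self.table.index[mask]]

    @property
    def inhibitor_dependent_genes(self) -> list[str]:
        mask = self.table["inhibitor_dependent"]
        return [str(g) for g in self.table.index[mask]]

    def class_counts(self) -> dict[str, int]:
        counts = self.table["gene_class"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CLASSES}


def generate_design(n_replicates: int, include_inhibitor_arm: bool = False) -> SampleDesign:
    """Build the factorial sample layout.

    Returns 2 x 2 x 2 x ``n_replicates`` samples over genotype, drug and
    ligand, plus a vector-genotype inhibitor arm (2 drug x 2 ligand x
    ``n_replicates``) when ``include_inhibitor_arm`` is set.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for genotype in GENOTYPES:
        for drug in DRUGS:
            for ligand in LIGANDS:
                for rep in range(1, n_replicates + 1):
                    sid = f"{genotype}.{drug}.{ligand}.r{rep}"
                    rows.append((sid, genotype, drug, ligand, "none", rep))
    if include_inhibitor_arm:
        for drug in DRUGS:
            for ligand in LIGANDS:
                for rep in range(1, n_replicates + 1):
                    sid = f"vector.{drug}.{ligand}.SB203580.r{rep}"
                    rows.append((sid, "vector", drug, ligand, "SB203580", rep))
    table = pd.DataFrame(
        rows, columns=["sample_id", "genotype", "drug", "ligand", "inhibitor", "replicate"]
    ).set_index("sample_id")
    return SampleDesign(table)


def _allocate_classes(config: SimConfig) -> list[str]:
    """Largest-remainder apportionment so counts match fractions exactly."""
    fractions = {c: config.class_fractions.get(c, 0.0) for c in CLASSES}
    raw = {c: fractions[c] * config.n_genes for c in CLASSES}
    counts = {c: int(np.floor(raw[c])) for c in CLASSES}
    short = config.n_genes - sum(counts.values())
    remainders = sorted(
        CLASSES, key=lambda c: (-(raw[c] - counts[c]), CLASSES.index(c))
    )
    for c in remainders[:short]:
        counts[c] += 1
    labels: list[str] = []
    for c in CLASSES:
        labels.extend([c] * counts[c])
    return labels


def generate_expression(
    config: SimConfig, design: SampleDesign
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a log2 expression matrix with planted class structure.

    The log2 expression of gene *g* in sample *s* is::

        baseline_g
        + p53(s) * drug_term_g(drug)
        + ligand_term_g(ligand)
        + p53(s) * I[combo] * (interaction_g - I[inhibitor] * attenuation_g)
        + Normal(0, noise_sd)

    where ``p53(s)`` is 1 in the vector genotype and
    ``1 - p53_knockdown_efficiency`` in the p53i genotype, and the
    attenuation term applies only to inhibitor-dependent genes. Identical
    ``(config, design)`` inputs reproduce the matrix bitwise.
    """
    for genotype in GENOTYPES:
        for drug in DRUGS:
            for ligand in LIGANDS:
                if not design.samples_for(genotype, drug, ligand, "none"):
                    raise ValueError(
                        f"design lacks condition ({genotype}, {drug}, {ligand})"
                    )
    rng = np.random.default_rng(config.seed)
    labels = _allocate_classes(config)
    n = config.n_genes
    width = max(4, len(str(n)))
    gene_ids = [f"G{idx:0{width}d}" for idx in range(1, n + 1)]

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    cls = np.asarray(labels)
    eff_drug = np.zeros(n)
    eff_ligand = np.zeros(n)
    eff_inter = np.zeros(n)
    inhib_dep = cls == "synergistic_inhibitor_dependent"
    eff_drug[cls == "p53_induced"] = config.effect_drug
    eff_drug[cls == "p53_repressed"] = -config.effect_drug
    eff_ligand[cls == "ligand_induced"] = config.effect_ligand
    syn = np.isin(cls, SYNERGISTIC_CLASSES)
    eff_drug[syn] = config.effect_drug
    eff_ligand[syn] = config.effect_ligand
    eff_inter[syn] = config.effect_interaction

    sample_ids = design.sample_ids
    tbl = design.table
    p53 = np.where(
        tbl["genotype"].to_numpy() == "vector", 1.0, 1.0 - config.p53_knockdown_efficiency
    )
    has_drug = (tbl["drug"].to_numpy() == "Nutlin").astype(float)
    has_ligand = (tbl["ligand"].to_numpy() == "flagellin").astype(float)
    combo = has_drug * has_ligand
    has_inhib = (tbl["inhibitor"].to_numpy() != "none").astype(float)

    # genes x samples deterministic signal
    attenuation = np.where(inhib_dep, config.inhibitor_attenuation, 0.0)
    signal = (
        baselines[:, None]
        + np.outer(eff_drug, p53 * has_drug)
        + np.outer(eff_ligand, has_ligand)
        + np.outer(eff_inter, p53 * combo)
        - np.outer(attenuation, p53 * combo * has_inhib)
    )
    noise = rng.normal(0.0, config.noise_sd, size=signal.shape) if config.noise_sd > 0 else 0.0
    values = pd.DataFrame(signal + noise, index=gene_ids, columns=sample_ids)

    truth = pd.DataFrame(
        {
            "gene_class": cls,
            "effect_drug": eff_drug,
            "effect_ligand": eff_ligand,
            "effect_interaction": eff_inter,
            "inhibitor_dependent": inhib_dep,
        },
        index=gene_ids,
    )
    return ExpressionMatrix(values, "log2"), SyntheticTruth(truth)


def generate_gene_sets(
    truth: SyntheticTruth,
    n_sets: int,
    set_size: int,
    planted_enrichment_fraction: float,
    seed: int,
    enriched_class: str = "synergistic",
    n_enriched: int = 3,
) -> GeneSetCollection:
    """Emit ``n_sets`` gene sets, the first ``n_enriched`` enriched for a class.

    Enriched sets draw ``planted_enrichment_fraction`` of their members from
    the designated truth class (``"synergistic"`` pools both synergistic
    subclasses) and the remainder uniformly from the other genes; background
    sets are uniform draws. Set names carry the planted class.
    """
    if not 0.0 <= planted_enrichment_fraction <= 1.0:
        raise ValueError("planted_enrichment_fraction must be in [0, 1]")
    all_genes = [str(g) for g in truth.table.index]
    if set_size > len(all_genes):
        raise ValueError("set_size exceeds number of genes")
    if n_sets < 0:
        raise ValueError("n_sets must be >= 0")
    n_enriched = min(n_enriched, n_sets)
    if enriched_class == "synergistic":
        class_genes = truth.synergistic_genes
    else:
        class_genes = truth.genes_in_class(enriched_class)
    other_genes = [g for g in all_genes if g not in set(class_genes)]
    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    for i in range(n_sets):
        if i < n_enriched and class_genes:
            n_from_class = min(
                int(round(planted_enrichment_fraction * set_size)), len(class_genes)
            )
            n_bg = set_size - n_from_class
            members = list(rng.choice(class_genes, size=n_from_class, replace=False))
            if n_bg > 0:
                members += list(rng.choice(other_genes, size=n_bg, replace=False))
            name = f"planted_{enriched_class}_{i + 1:02d}"
            desc = f"enriched for {enriched_class} (fraction {planted_enrichment_fraction})"
        else:
            members = list(rng.choice(all_genes, size=set_size, replace=False))
            name = f"background_{i + 1:03d}"
            desc = "uniform background set"
        collection.add(name, sorted(members), desc)
    return collection


def generate_signatures(
    truth: SyntheticTruth,
    n_signatures: int,
    overlap_fractions: list[float] | float,
    seed: int,
    signature_size: int = 50,
) -> GeneSetCollection:
    """Synthetic response signatures with controlled synergistic-gene overlap.

    Signature *i* contains ``overlap_fractions[i]`` of the planted
    synergistic genes (rounded), padded with background genes up to
    ``signature_size`` (or the overlap count, whichever is larger).
    """
    if np.isscalar(overlap_fractions):
        overlap_fractions = [float(overlap_fractions)] * n_signatures
    if len(overlap_fractions) != n_signatures:
        raise ValueError("need one overlap fraction per signature")
    for f in overlap_fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"overlap fraction {f} outside [0, 1]")
    syn = truth.synergistic_genes
    all_genes = [str(g) for g in truth.table.index]
    other = [g for g in all_genes if g not in set(syn)]
    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    for i, frac in enumerate(overlap_fractions):
        n_overlap = int(round(frac * len(syn)))
        members = list(rng.choice(syn, size=n_overlap, replace=False)) if n_overlap else []
        n_bg = max(signature_size - n_overlap, 0)
        if n_bg > len(other):
            raise ValueError("signature_size too large for available background genes")
        if n_bg:
            members += list(rng.choice(other, size=n_bg, replace=False))
        if not members:
            warnings.warn(f"signature {i + 1} is empty; padding with one background gene")
            members = list(rng.choice(other, size=1, replace=False))
        collection.add(
            f"signature_{i + 1:02d}",
            sorted(members),
            f"synthetic response signature, overlap fraction {frac}",
        )
    return collection
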
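"""End-to-end orchestration: simulate/load -> preprocess -> cluster ->
synergy -> enrichment, with a manifest that records everything needed to
re-execute the run.

Outputs in the run directory (all deterministic for a fixed config/seed):

* ``expression.tsv``, ``design.tsv`` (+ ``truth.tsv``, ``gene_sets.gmt``,
  ``signatures.gmt`` in simulate mode)
* ``filtered.tsv`` — SD-filtered, centered/normalized matrix
* ``clustered.cdt`` / ``clustered.gtr`` — TreeView pair
* ``cluster_assignments.tsv`` — flat clusters with contrast labels
* ``synergy.tsv`` — fold changes, SF, criterion flags, classification
* ``differential_drug_up.txt`` etc. — threshold gene lists
* ``enrichment.tsv``, ``signature_overlap.tsv``
* ``manifest.json`` — config echo, seed, versions, checksums, stage counts
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cluster as _cluster
from . import enrich as _enrich
from . import io_formats as io
from . import preprocess as _preprocess
from . import simdata as _simdata
from . import synergy as _synergy
from .containers import ExpressionMatrix, GeneSetCollection, SampleDesign
from .preprocess import PreprocessParams
from .simdata import SimConfig
from .synergy import SynergyCriteria


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Exactly one of ``simulate`` (a :class:`~synerscan.simdata.SimConfig`)
    or the input paths (``matrix_path`` + ``design_path``) must be given.
    """

    out_dir: str
    seed: int = 0
    simulate: SimConfig | None = None
    matrix_path: str | None = None
    design_path: str | None = None
    matrix_scale: str = "log2"
    gene_sets_path: str | None = None
    signatures_path: str | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    criteria: SynergyCriteria = field(default_factory=SynergyCriteria)
    cluster_k: int = 6
    label_margin: float = 0.5
    attenuation_fold: float = 2.0
    up_fold: float = 2.0
    down_fold: float = 2.0
    enrichment_universe: str = "all"  # "all" | "filtered"
    collapse_probes: str | None = None  # None | "max_sd" | "mean"

    def __post_init__(self) -> None:
        sim_mode = self.simulate is not None
        input_mode = self.matrix_path is not None or self.design_path is not None
        if sim_mode and input_mode:
            raise ValueError("config must give either a simulate block or input paths, not both")
        if not sim_mode:
            if self.matrix_path is None or self.design_path is None:
                raise ValueError("input mode needs both matrix_path and design_path")
            for p in (self.matrix_path, self.design_path, self.gene_sets_path,
                      self.signatures_path):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")
        if self.collapse_probes not in (None, "max_sd", "mean"):
            raise ValueError("collapse_probes must be None, 'max_sd' or 'mean'")
        if self.enrichment_universe not in ("all", "filtered"):
            raise ValueError("enrichment_universe must be 'all' or 'filtered'")


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    pre = raw.pop("preprocess", None)
    crit = raw.pop("criteria", None)
    cfg = RunConfig(
        simulate=SimConfig(**sim) if sim is not None else None,
        preprocess=PreprocessParams(**pre) if pre is not None else PreprocessParams(),
        criteria=SynergyCriteria(**crit) if crit is not None else SynergyCriteria(),
        **raw,
    )
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def collapse_probe_rows(
    matrix: ExpressionMatrix, gene_of_probe: dict[str, str], rule: str = "max_sd"
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    ``max_sd`` keeps the probe with the largest across-sample SD per gene
    (ties to the first probe in row order); ``mean`` averages probes.
    """
    if rule not in ("max_sd", "mean"):
        raise ValueError("rule must be 'max_sd' or 'mean'")
    values = matrix.values
    genes = pd.Series([gene_of_probe.get(p, p) for p in values.index], index=values.index)
    if rule == "mean":
        collapsed = values.groupby(genes, sort=False).mean()
    else:
        sds = values.std(axis=1, ddof=1)
        order = np.arange(len(values))
        pick = (
            pd.DataFrame({"gene": genes.to_numpy(), "sd": sds.to_numpy(), "order": order})
            .sort_values(["gene", "sd", "order"], ascending=[True, False, True], kind="mergesort")
            .groupby("gene", sort=False)
            .head(1)
            .sort_values("order")
        )
        collapsed = values.iloc[pick["order"].to_numpy()].copy()
        collapsed.index = pick["gene"].to_numpy()
    return ExpressionMatrix(collapsed, matrix.scale)


class StageError(RuntimeError):
    """Wraps an exception with the name of the failing pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis and write all artifacts to ``out_dir``.

    Returns a result bundle with the in-memory tables and the manifest.
    Re-running with the same config and seed reproduces byte-identical
    output files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, Any] = {}
    input_checksums: dict[str, str] = {}
    truth = None
    gene_sets: GeneSetCollection | None = None
    signatures: GeneSetCollection | None = None

    # ---- acquire inputs -------------------------------------------------
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            has_inhibitor = [
                c
                for c in ("synergistic_inhibitor_dependent",)
                if sim.class_fractions.get(c, 0.0) > 0
            ]
            design = _simdata.generate_design(
                sim.n_replicates, include_inhibitor_arm=bool(has_inhibitor)
            )
            matrix, truth = _simdata.generate_expression(sim, design)
            gene_sets = _simdata.generate_gene_sets(
                truth, n_sets=20, set_size=50, planted_enrichment_fraction=0.8,
                seed=config.seed + 1,
            )
            signatures = _simdata.generate_signatures(
                truth, n_signatures=5,
                overlap_fractions=[0.5, 0.4, 0.3, 0.2, 0.0],
                seed=config.seed + 2,
            )
            io.write_expression(matrix, out / "expression.tsv")
            io.write_design(design, out / "design.tsv")
            truth_df = truth.table.copy()
            truth_df.index.name = "gene_id"
            io.write_table(truth_df, out / "truth.tsv", index_label="gene_id")
            io.write_gmt(gene_sets, out / "gene_sets.gmt")
            io.write_gmt(signatures, out / "signatures.gmt")
        else:
            matrix = io.read_expression(config.matrix_path, config.matrix_scale)
            design = io.read_design(config.design_path)
            input_checksums[config.matrix_path] = _sha256(Path(config.matrix_path))
            input_checksums[config.design_path] = _sha256(Path(config.design_path))
            if config.gene_sets_path:
                gene_sets = io.read_gmt(config.gene_sets_path)
                input_checksums[config.gene_sets_path] = _sha256(Path(config.gene_sets_path))
            if config.signatures_path:
                signatures = io.read_gmt(config.signatures_path)
                input_checksums[config.signatures_path] = _sha256(Path(config.signatures_path))
    except Exception as exc:  # noqa: BLE001
        raise StageError("input", exc) from exc
    counts["genes_in"] = matrix.n_genes
    counts["samples_in"] = matrix.n_samples

    # ---- preprocess -----------------------------------------------------
    try:
        if matrix.scale == "linear":
            matrix = _preprocess.log2_transform(matrix, config.preprocess.pseudocount)
        filtered = _preprocess.sd_filter(
            matrix, config.preprocess.sd_threshold, ddof=config.preprocess.sd_ddof
        )
        centered = _preprocess.center_and_normalize(filtered, config.preprocess)
        io.write_expression(centered, out / "filtered.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", exc) from exc
    counts["genes_after_sd_filter"] = filtered.n_genes

    # ---- cluster --------------------------------------------------------
    try:
        k = min(config.cluster_k, centered.n_genes)
        tree = _cluster.average_linkage(centered)
        assignment = _cluster.cut_tree(tree, k=k)
        # contrast labels use centered but unscaled log2 values so the
        # margin stays in log2 units
        centered_only = _preprocess.center_and_normalize(
            filtered, dataclasses.replace(config.preprocess, scale_rows=False)
        )
        assignment = _cluster.label_clusters(
            assignment, centered_only, design, margin=config.label_margin
        )
        io.write_cdt_gtr(centered, tree, out / "clustered")
        io.write_table(assignment.to_frame(), out / "cluster_assignments.tsv",
                       index_label="gene_id")
    except Exception as exc:  # noqa: BLE001
        raise StageError("cluster", exc) from exc
    counts["clusters"] = len(assignment.cluster_ids)
    counts["cluster_labels"] = {
        str(c): assignment.label_of(c) for c in assignment.cluster_ids
    }

    # ---- synergy --------------------------------------------------------
    try:
        fc_vector = _synergy.condition_fold_changes(matrix, design, "vector")
        fc_p53i = _synergy.condition_fold_changes(matrix, design, "p53i")
        results = _synergy.classify_synergistic(fc_vector, fc_p53i, config.criteria)
        if design.has_inhibitor_arm():
            fc_inh = _synergy.condition_fold_changes(
                matrix, design, "vector", inhibitor="SB203580"
            )
            results = _synergy.classify_inhibitor_dependent(
                results, fc_inh, fc_vector, config.attenuation_fold
            )
        io.write_table(results, out / "synergy.tsv", index_label="gene_id")
        lists = _synergy.differential_lists(fc_vector, config.up_fold, config.down_fold)
        for name, genes in lists.items():
            io.write_gene_list(genes, out / f"differential_{name}.txt")
    except Exception as exc:  # noqa: BLE001
        raise StageError("synergy", exc) from exc
    targets = _synergy.synergistic_targets(results)
    counts["criterion_pass"] = {
        "c1_combo_over_singles": int(results["c1_combo_over_singles"].sum()),
        "c2_synergy_factor": int(results["c2_synergy_factor"].sum()),
        "c3_genotype_dependence": int(results["c3_genotype_dependence"].sum()),
    }
    counts["synergistic_targets"] = len(targets)
    if "inhibitor_dependent" in results.columns:
        counts["inhibitor_dependent_targets"] = int(results["inhibitor_dependent"].sum())
    counts["differential_list_sizes"] = {k: len(v) for k, v in lists.items()}

    # ---- enrichment -----------------------------------------------------
    enrichment = None
    overlap = None
    try:
        universe = (
            filtered.gene_ids if config.enrichment_universe == "filtered" else matrix.gene_ids
        )
        query = [g for g in targets if g in set(universe)]
        if gene_sets is not None and query:
            enrichment = _enrich.enrich_sets(query, gene_sets, universe)
            io.write_table(enrichment, out / "enrichment.tsv")
        if signatures is not None and query:
            overlap = _enrich.signature_overlap(query, signatures, universe)
            io.write_table(overlap, out / "signature_overlap.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrich", exc) from exc

    # ---- manifest -------------------------------------------------------
    manifest = {
        "synerscan_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "config": _config_echo(config),
        "input_checksums": input_checksums,
        "stage_counts": counts,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "matrix": matrix,
        "filtered": centered,
        "tree": tree,
        "assignment": assignment,
        "synergy": results,
        "targets": targets,
        "differential": lists,
        "enrichment": enrichment,
        "signature_overlap": overlap,
        "truth": truth,
        "manifest": manifest,
    }


def _config_echo(config: RunConfig) -> dict[str, Any]:
    def encode(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        return obj

    return encode(config)
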
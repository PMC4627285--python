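"""Core in-memory containers shared by every pipeline stage.

The three containers wrap :class:`pandas.DataFrame` objects and enforce the
structural invariants the downstream stages rely on (unique identifiers,
finite values, declared expression scale, complete factorial cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENOTYPES = ("vector", "p53i")
DRUGS = ("DMSO", "Nutlin")
LIGANDS = ("none", "flagellin")
INHIBITORS = ("none", "SB203580")

DESIGN_COLUMNS = ("genotype", "drug", "ligand", "inhibitor", "replicate")


class FormatError(ValueError):
    """A file or table violates its declared on-disk format."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for lab in labels:
        if lab in seen:
            dups.append(lab)
        seen.add(lab)
    if dups:
        raise FormatError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared scale.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as the columns. Row/column order is meaningful and preserved.
    scale
        ``"linear"`` or ``"log2"``. Linear-scale values must be strictly
        positive so a log transform is always defined.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise FormatError("expression matrix has an empty data section")
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "sample IDs")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if self.scale == "linear" and np.any(arr <= 0):
            bad = np.argwhere(arr <= 0)[0]
            raise FormatError(
                f"non-positive value under scale=linear at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.scale)


@dataclass
class SampleDesign:
    """Per-sample factor assignments for the 2x2x2 (+ inhibitor arm) design.

    ``table`` is indexed by sample ID with columns genotype, drug, ligand,
    inhibitor and replicate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        _check_unique(self.table.index, "sample IDs")
        for col, levels in (
            ("genotype", GENOTYPES),
            ("drug", DRUGS),
            ("ligand", LIGANDS),
            ("inhibitor", INHIBITORS),
        ):
            bad = set(self.table[col]) - set(levels)
            if bad:
                raise FormatError(f"unknown {col} level(s): {sorted(bad)}")
        self.table = self.table.copy()
        self.table["replicate"] = self.table["replicate"].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    def samples_for(
        self,
        genotype: str | None = None,
        drug: str | None = None,
        ligand: str | None = None,
        inhibitor: str | None = None,
    ) -> list[str]:
        """Sample IDs matching every specified factor level."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in (
            ("genotype", genotype),
            ("drug", drug),
            ("ligand", ligand),
            ("inhibitor", inhibitor),
        ):
            if val is not None:
                mask &= self.table[col] == val
        return [str(s) for s in self.table.index[mask]]

    def has_inhibitor_arm(self) -> bool:
        return bool((self.table["inhibitor"] != "none").any())


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets with free-text descriptions.

    Set names are unique and sets are non-empty; membership is stored as a
    list in input order but queried as a set.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> set[str]:
        return set(self.sets[name])

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        members = list(dict.fromkeys(members))  # dedupe, keep order
        if not members:
            raise FormatError(f"gene set {name!r} is empty")
        self.sets[name] = members
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def items(self) -> Iterable[tuple[str, list[str]]]:
        return self.sets.items()
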
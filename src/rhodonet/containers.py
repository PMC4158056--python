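"""Core in-memory containers shared across the pipeline stages.

The central object is :class:`ExprMatrix`, a labelled gene-by-condition
matrix with a standardization tag recording which normalization steps have
been applied.  Module assignments, ortholog maps and gene-set collections
are thin validated wrappers around pandas structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STANDARDIZATION_TAGS = ("raw", "log2", "averaged", "robust_z", "z")

#: Conventional size-ordered module colour palette (largest module first).
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
    "lightsteelblue1", "lightcyan1", "ivory", "floralwhite", "darkorange2",
    "brown4", "bisque4", "darkslateblue", "plum2", "thistle2", "thistle1",
    "salmon4", "palevioletred3", "navajowhite2", "maroon", "lightpink4",
    "lavenderblush3", "honeydew1", "darkseagreen4", "coral1",
)

UNASSIGNED_COLOR = "grey"


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class ExprMatrix:
    """Gene-by-condition expression matrix with label bookkeeping.

    Parameters
    ----------
    data
        DataFrame with unique gene ids as index and unique condition (or
        sample) ids as columns.  Missing values are NaN.
    standardization
        One of ``raw``, ``log2``, ``averaged``, ``robust_z``, ``z``.
    """

    data: pd.DataFrame
    standardization: str = "raw"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("ExprMatrix.data must be a pandas DataFrame")
        if self.standardization not in STANDARDIZATION_TAGS:
            raise ValidationError(
                f"unknown standardization tag {self.standardization!r}; "
                f"expected one of {STANDARDIZATION_TAGS}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate condition ids: {dups}")
        self.data = self.data.astype(float)

    # -- accessors -----------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def condition_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def has_missing(self) -> bool:
        return bool(self.data.isna().to_numpy().any())

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    # -- manipulation --------------------------------------------------
    def subset_genes(self, genes: Sequence) -> "ExprMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes not present: {missing[:5]}")
        return replace(self, data=self.data.loc[list(genes)].copy())

    def subset_conditions(self, conditions: Sequence) -> "ExprMatrix":
        missing = [c for c in conditions if c not in self.data.columns]
        if missing:
            raise ValidationError(f"conditions not present: {missing[:5]}")
        return replace(self, data=self.data[list(conditions)].copy())

    def rename_genes(self, mapping: Mapping) -> "ExprMatrix":
        return replace(self, data=self.data.rename(index=dict(mapping)))

    def copy(self) -> "ExprMatrix":
        return replace(self, data=self.data.copy())


@dataclass
class SampleSheet:
    """Maps sample columns to conditions and, optionally, probes to genes.

    ``samples`` has index sample_id and columns ``condition`` and
    ``replicate``; ``probe_map`` (optional) has columns ``probe`` and
    ``gene`` and may contain repeated probes (multi-gene hits).
    """

    samples: pd.DataFrame
    probe_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"condition"}
        if not required.issubset(self.samples.columns):
            raise ValidationError("sample sheet needs a 'condition' column")
        if self.samples.index.has_duplicates:
            raise ValidationError("sample ids must be unique")
        if self.probe_map is not None:
            if not {"probe", "gene"}.issubset(self.probe_map.columns):
                raise ValidationError("probe map needs 'probe' and 'gene' columns")

    def condition_of(self, sample_id) -> str:
        return self.samples.loc[sample_id, "condition"]

    @property
    def conditions(self) -> list:
        # preserve first-appearance order
        return list(dict.fromkeys(self.samples["condition"]))


@dataclass
class ModulePartition:
    """Assignment of every gene to an integer module label (0 = unassigned)."""

    labels: pd.Series

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValidationError("partition gene ids must be unique")
        self.labels = self.labels.astype(int)
        if (self.labels < 0).any():
            raise ValidationError("module labels must be non-negative")

    @property
    def gene_ids(self) -> list:
        return list(self.labels.index)

    @property
    def module_labels(self) -> list[int]:
        """Nonzero labels sorted ascending."""
        return sorted(l for l in self.labels.unique() if l != 0)

    def members(self, label: int) -> list:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> dict[int, int]:
        return {l: int((self.labels == l).sum()) for l in self.module_labels}

    def color_of(self, label: int) -> str:
        if label == 0:
            return UNASSIGNED_COLOR
        idx = label - 1
        if idx < len(MODULE_COLORS):
            return MODULE_COLORS[idx]
        return f"module{label}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module": self.labels,
                "color": [self.color_of(l) for l in self.labels],
            },
            index=self.labels.index,
        )

    def restrict(self, genes: Sequence) -> "ModulePartition":
        return ModulePartition(self.labels.loc[list(genes)].copy())


@dataclass
class OrthologMap:
    """One-to-one gene correspondence between a reference and a test species."""

    pairs: pd.DataFrame  # columns: ref, test

    def __post_init__(self) -> None:
        if not {"ref", "test"}.issubset(self.pairs.columns):
            raise ValidationError("ortholog map needs 'ref' and 'test' columns")
        for col in ("ref", "test"):
            if self.pairs[col].duplicated().any():
                dups = self.pairs[col][self.pairs[col].duplicated()].unique().tolist()
                raise ValidationError(
                    f"ortholog map is not one-to-one in column {col!r}: {dups[:5]}"
                )
        self.pairs = self.pairs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ref_genes(self) -> list:
        return list(self.pairs["ref"])

    @property
    def test_genes(self) -> list:
        return list(self.pairs["test"])

    def test_of_ref(self) -> dict:
        return dict(zip(self.pairs["ref"], self.pairs["test"]))

    @classmethod
    def identity(cls, genes: Iterable) -> "OrthologMap":
        genes = list(genes)
        return cls(pd.DataFrame({"ref": genes, "test": genes}))


@dataclass
class GeneSetCollection:
    """Named gene sets with a category tag per set."""

    sets: dict[str, set] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)
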
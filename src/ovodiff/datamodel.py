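"""Shared data containers for the superovulation expression pipeline.

The study design compares two ovulation treatments (hormonal superovulation
vs. natural ovulation) across seven ordered developmental stages of the
mouse oocyte and its derivative preimplantation embryos, in two molecular
modalities: protein abundances (iBAQ/riBAQ intensities) and transcript
counts.  Everything downstream — normalization, the stage-paired exact
permutation test, clustering/PCA diagnostics, enrichment — operates on the
:class:`ExpressionMatrix` defined here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Ordered developmental stages, oocyte through blastocyst.
STAGES: tuple[str, ...] = (
    "oocyte",
    "1-cell",
    "2-cell",
    "4-cell",
    "8-cell",
    "morula",
    "blastocyst",
)

#: The two ovulation treatments being contrasted.
TREATMENTS: tuple[str, ...] = ("superovulation", "natural")

SCALES: tuple[str, ...] = ("linear", "log10", "log2")
MODALITIES: tuple[str, ...] = ("protein", "transcript")

DESIGN_COLUMNS: tuple[str, ...] = ("stage", "treatment", "replicate")


class DesignError(ValueError):
    """Raised when a sample-design table violates the design contract."""


def make_design(
    stages: Sequence[str] = STAGES,
    treatments: Sequence[str] = TREATMENTS,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Build a full-factorial sample design (stage x treatment x replicate).

    Sample ids are ``"<stage>_<treatment>_r<replicate>"``.  Returns a frame
    indexed by sample id with columns ``stage``, ``treatment``,
    ``replicate``.
    """
    rows = []
    for stage in stages:
        for treatment in treatments:
            for rep in range(1, n_replicates + 1):
                rows.append((f"{stage}_{treatment}_r{rep}", stage, treatment, rep))
    design = pd.DataFrame(rows, columns=["sample_id", *DESIGN_COLUMNS])
    return validate_design(design)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample design table.

    Accepts a frame either indexed by sample id or carrying a ``sample_id``
    column; returns a copy indexed by sample id.  Enforces the fixed stage
    and treatment vocabularies, unique sample ids and positive integer
    replicate numbers.
    """
    design = design.copy()
    if "sample_id" in design.columns:
        design = design.set_index("sample_id")
    design.index = design.index.astype(str)
    design.index.name = "sample_id"
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise DesignError(f"design table lacks columns: {sorted(missing)}")
    if design.index.duplicated().any():
        dupes = design.index[design.index.duplicated()].unique().tolist()
        raise DesignError(f"duplicate sample ids in design: {dupes}")
    bad_stage = set(design["stage"]) - set(STAGES)
    if bad_stage:
        raise DesignError(f"unknown stages {sorted(bad_stage)}; expected one of {STAGES}")
    bad_treat = set(design["treatment"]) - set(TREATMENTS)
    if bad_treat:
        raise DesignError(
            f"unknown treatments {sorted(bad_treat)}; expected one of {TREATMENTS}"
        )
    reps = pd.to_numeric(design["replicate"], errors="coerce")
    if reps.isna().any() or (reps <= 0).any() or (reps != reps.round()).any():
        raise DesignError("replicate numbers must be positive integers")
    design["replicate"] = reps.astype(int)
    return design[list(DESIGN_COLUMNS)]


def require_complete_design(design: pd.DataFrame) -> None:
    """Error unless every (stage, treatment) cell has at least one sample."""
    present = set(zip(design["stage"], design["treatment"]))
    expected = {(s, t) for s in STAGES for t in TREATMENTS}
    missing = expected - present
    if missing:
        raise DesignError(f"design missing (stage, treatment) cells: {sorted(missing)}")


@dataclass
class ExpressionMatrix:
    """Features x samples expression table with an explicit detection mask.

    Parameters
    ----------
    values
        Numeric frame, features as rows (unique ids), samples as columns.
        On ``linear`` scale undetected cells are stored as 0; on log scales
        they are stored as NaN.
    detected
        Boolean frame, same shape, True where a value was observed.
    design
        Sample design indexed by sample id, aligned with ``values.columns``.
    scale
        One of ``linear``, ``log10``, ``log2``.
    modality
        ``protein`` or ``transcript``.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    design: pd.DataFrame
    scale: str = "linear"
    modality: str = "protein"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        self.design = validate_design(self.design)
        self.values = self.values.astype(float)
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if list(self.values.columns) != list(self.design.index):
            raise ValueError("values columns must match design sample ids in order")
        if self.detected.shape != self.values.shape:
            raise ValueError("detected mask shape differs from values shape")
        self.detected = pd.DataFrame(
            np.asarray(self.detected, dtype=bool),
            index=self.values.index,
            columns=self.values.columns,
        )
        vals = self.values.to_numpy()
        det = self.detected.to_numpy()
        if not np.isfinite(vals[det]).all():
            raise ValueError("detected values must be finite")
        if self.scale == "linear":
            if (vals[det] <= 0).any():
                raise ValueError("linear-scale detected values must be > 0")
            if (vals[~det] != 0).any():
                raise ValueError("linear-scale undetected values must be stored as 0")

    # -- constructors -------------------------------------------------

    @classmethod
    def from_values(
        cls,
        values: pd.DataFrame,
        design: pd.DataFrame,
        scale: str = "linear",
        modality: str = "protein",
        detected: pd.DataFrame | None = None,
    ) -> "ExpressionMatrix":
        """Build a matrix, inferring the detection mask when absent.

        On linear scale detection is defined as value > 0 (missing/blank
        cells count as 0); on log scales as non-NaN.
        """
        values = values.astype(float)
        if detected is None:
            if scale == "linear":
                detected = values.fillna(0.0) > 0
                values = values.fillna(0.0)
            else:
                detected = values.notna()
        return cls(values, detected, design, scale=scale, modality=modality)

    # -- basics -------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.detected.copy(),
            self.design.copy(),
            scale=self.scale,
            modality=self.modality,
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        unknown = set(ids) - set(self.values.index)
        if unknown:
            raise KeyError(f"unknown feature ids: {sorted(unknown)[:5]}")
        return ExpressionMatrix(
            self.values.loc[ids],
            self.detected.loc[ids],
            self.design,
            scale=self.scale,
            modality=self.modality,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            self.values[ids],
            self.detected[ids],
            self.design.loc[ids],
            scale=self.scale,
            modality=self.modality,
        )

    def group_columns(self, by: Sequence[str] = ("stage", "treatment")) -> dict:
        """Map each design-cell tuple to its list of sample ids (design order)."""
        groups: dict[tuple, list[str]] = {}
        for sid, row in self.design.iterrows():
            key = tuple(row[c] for c in by)
            groups.setdefault(key, []).append(sid)
        return groups

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        """Return a copy with replaced values (same mask/design)."""
        return ExpressionMatrix(
            values,
            self.detected.copy(),
            self.design.copy(),
            scale=self.scale if scale is None else scale,
            modality=self.modality,
        )


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.term_id!r} has duplicate members")


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets (e.g. Mammalian Phenotype terms)."""

    terms: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate term ids in collection")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]


@dataclass
class ContingencyTable:
    """A k x 2 table of non-negative integer counts with labelled margins."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("contingency table must be k x 2")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or (self.counts < 0).any():
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)
        if self.row_labels is None:
            self.row_labels = [f"row{i}" for i in range(self.counts.shape[0])]
        if self.col_labels is None:
            self.col_labels = [f"col{i}" for i in range(2)]
        if (self.counts.sum(axis=1) == 0).any() or (self.counts.sum(axis=0) == 0).any():
            raise ValueError("every row and column margin must be positive")
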
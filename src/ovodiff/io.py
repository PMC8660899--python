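"""Readers and writers for every external format the pipeline touches.

Expression tables and sample designs are tab-delimited text; gene-set
collections are GMT; dendrograms are serialized as Newick.  All tables are
written tab-delimited with a fixed column order and '.' decimal separator
so that regression tests can be bit-exact.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    validate_design,
)
from .structure import Dendrogram

log = logging.getLogger(__name__)


def read_design(path) -> pd.DataFrame:
    """Read a sample-design TSV (sample_id, stage, treatment, replicate)."""
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_design(design)


def write_design(design: pd.DataFrame, path) -> None:
    design = validate_design(design)
    design.reset_index().to_csv(path, sep="\t", index=False)


def read_expression_table(
    path,
    design_path,
    value_prefix: str = "",
    feature_column: str | int = 0,
    modality: str = "protein",
) -> ExpressionMatrix:
    """Read a linear-scale expression TSV against a sample design.

    The file must carry one feature-id column (``feature_column``, by name
    or position) and one numeric column per design sample, named
    ``value_prefix + sample_id`` (MaxQuant-style ``iBAQ <sample>`` headers
    are matched by setting ``value_prefix="iBAQ "``).  Empty, missing and
    zero cells are marked undetected.

    Raises a hard error naming the offender on unmatched sample columns,
    duplicate feature ids, or non-numeric cells (with row/column
    coordinates).
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if isinstance(feature_column, int):
        feature_column = table.columns[feature_column]
    if feature_column not in table.columns:
        raise ValueError(f"feature-id column {feature_column!r} not in {path}")
    design = read_design(design_path)

    feature_ids = table[feature_column].astype(str)
    dup = feature_ids[feature_ids.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate feature ids in {path}: {dup[:5]}")

    columns = {}
    for sid in design.index:
        col = value_prefix + sid
        if col not in table.columns:
            raise ValueError(
                f"design sample {sid!r} has no column {col!r} in {path}"
            )
        raw = table[col]
        numeric = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = numeric.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric cell in {path} at row {row + 2} (feature "
                f"{feature_ids.iloc[row]!r}), column {col!r}: {raw.iloc[row]!r}"
            )
        # parse via float() for correctly-rounded (bit-exact) round-trips
        columns[sid] = np.array(
            [
                float(s) if isinstance(s, str) and s.strip() else np.nan
                for s in raw
            ]
        )
    values = pd.DataFrame(columns)
    values.index = pd.Index(feature_ids, name="feature_id")
    if (values.fillna(0.0).to_numpy() < 0).any():
        raise ValueError(f"negative intensities in {path}")
    return ExpressionMatrix.from_values(
        values, design, scale="linear", modality=modality
    )


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV; undetected cells become empty fields.

    Floats are rendered with ``repr`` precision so a write -> read
    round-trip is bit-identical.
    """
    out = matrix.values.copy()
    formatted = out.map(lambda v: "" if not np.isfinite(v) else np.format_float_positional(v, trim="-", precision=None))
    formatted = formatted.where(matrix.detected, "")
    formatted.index.name = "feature_id"
    formatted.reset_index().to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (term, description, tab-separated members).

    Duplicate members within a term are deduplicated with a logged warning;
    a line with fewer than three fields is an error naming the line number.
    """
    terms: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires term, description and at least one member"
                )
            term_id, name, *members = fields
            members = [m for m in members if m.strip()]
            seen: dict[str, None] = {}
            for m in members:
                if m in seen:
                    log.warning(
                        "GMT %s line %d: duplicate member %r in term %r dropped",
                        path, lineno, m, term_id,
                    )
                seen[m] = None
            terms.append(GeneSet(term_id, name, tuple(seen)))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term in collection:
            fh.write("\t".join([term.term_id, term.name, *term.members]) + "\n")


def _fmt_length(x: float) -> str:
    return np.format_float_positional(float(x), trim="-", precision=None)


def newick_string(tree: Dendrogram) -> str:
    """Render a merge tree as a Newick string with branch lengths.

    Branch lengths are differences of merge heights (leaves sit at height
    zero), so the leaf-to-root depth equals the root merge height.
    """
    n = len(tree.leaves)
    if len(set(tree.leaves)) != n:
        raise ValueError("duplicate leaf labels in dendrogram")
    if n == 1:
        return f"{tree.leaves[0]};"
    heights = {i: 0.0 for i in range(n)}
    labels = {i: str(tree.leaves[i]) for i in range(n)}
    for k, (a, b, h) in enumerate(tree.merges):
        node = n + k
        parts = []
        for child in (a, b):
            parts.append(f"{labels[child]}:{_fmt_length(h - heights[child])}")
        labels[node] = "(" + ",".join(parts) + ")"
        heights[node] = float(h)
    return labels[n + len(tree.merges) - 1] + ";"


def write_newick(tree: Dendrogram, path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")
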
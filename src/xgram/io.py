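"""Readers and writers for the toolkit's external file formats.

Formats handled:

* protein-protein association lists in the STRING ``protein.links``
  dialect (two node IDs plus an integer combined score on the 0-999
  scale, whitespace- or tab-separated, optional header);
* expression matrices as TSV, genes in rows, samples in columns,
  values pre-normalised (e.g. log2 RMA output);
* sample design tables (sample, condition, biological replicate,
  technical replicate);
* gene sets in GMT;
* gene orderings as TSV (position, gene, protein ID, relative
  position, optional statistics columns).

All readers validate their input and raise :class:`ParseError` or
:class:`ValidationError` with the offending location.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import GeneOrdering, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "GeneSet",
    "score_from_confidence",
    "read_interactions",
    "read_expression",
    "read_design",
    "read_gene_sets",
    "write_ordering",
    "read_ordering",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the location."""


class ValidationError(ValueError):
    """A file parsed but violates a format invariant."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line)."""

    name: str
    description: str
    members: frozenset

    def __len__(self) -> int:
        return len(self.members)


def score_from_confidence(confidence: float) -> int:
    """Map a confidence in [0, 1] to the integer 0-999 score scale.

    STRING files carry integer scores (800) while publications quote
    confidences (0.800); ceil with a tiny guard keeps 0.800 -> 800.
    """
    if not 0.0 <= confidence <= 1.0:
        raise ValidationError(f"confidence {confidence} outside [0, 1]")
    return min(int(math.ceil(1000.0 * confidence - 1e-9)), 999)


def read_interactions(path, score_min: int = 800) -> InteractionNetwork:
    """Read a STRING-style association file, keeping score >= score_min.

    Duplicate lines and both-direction listings collapse to a single
    undirected edge; self-loops are dropped with a warning; nodes left
    without any surviving edge are excluded (a gene enters the ordering
    only if its product has at least one association).
    """
    if not 0 <= score_min <= 999:
        raise ValidationError(f"score_min {score_min} outside [0, 999]")
    edges = set()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if lineno == 1 and fields[0].lower().startswith("protein1"):
                continue  # optional header
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 fields, got {len(fields)}"
                )
            a, b = fields[0], fields[1]
            try:
                score = int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer score {fields[2]!r}"
                ) from exc
            if not 0 <= score <= 999:
                raise ValidationError(
                    f"{path}: line {lineno}: score {score} outside [0, 999]"
                )
            if a == b:
                n_self += 1
                continue
            if score >= score_min:
                edges.add((a, b) if a < b else (b, a))
    if n_self:
        logger.warning("%s: dropped %d self-association line(s)", path, n_self)
    return InteractionNetwork.from_edges(edges)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV of pre-normalised expression values.

    Duplicate gene rows (multiple probe sets per gene) are collapsed by
    arithmetic mean with a logged count.  Non-numeric cells raise a
    :class:`ParseError` naming the cell.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")[1:]
    seen = set()
    for col in header:  # read_csv silently renames duplicates
        if col in seen:
            raise ValidationError(f"{path}: duplicate sample ID {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = header
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        out[col] = converted
    if out.index.duplicated().any():
        n_dup = int(out.index.duplicated().sum())
        logger.info("%s: mean-collapsing %d duplicate gene row(s)", path, n_dup)
        out = out.groupby(level=0, sort=False).mean()
    return out


def read_design(path) -> pd.DataFrame:
    """Read a design TSV with columns sample, condition, bio_rep, tech_rep."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    required = ["sample", "condition", "bio_rep", "tech_rep"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    df = df[required].copy()
    df["bio_rep"] = df["bio_rep"].astype(int)
    df["tech_rep"] = df["tech_rep"].astype(int)
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample ID {dup!r}")
    if df.duplicated(subset=["condition", "bio_rep", "tech_rep"]).any():
        raise ValidationError(
            f"{path}: duplicate (condition, bio_rep, tech_rep) triple"
        )
    return df


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ParseError(f"{path}: line {lineno}: gene set has no members")
            sets.append(GeneSet(name=fields[0], description=fields[1], members=members))
    return sets


def write_ordering(
    ordering: GeneOrdering,
    path,
    stats: pd.DataFrame | None = None,
    protein_ids: dict | None = None,
) -> None:
    """Write an ordering TSV: position, gene, protein ID, relative position.

    Extra per-position statistics columns (e.g. P-values per
    comparison) may be appended via ``stats`` (indexed 0..N-1 by list
    position).
    """
    n = ordering.n
    rel = ordering.relative_positions()
    rows = {
        "position": np.arange(1, n + 1),
        "gene": ordering.order,
        "protein_id": [
            (protein_ids or {}).get(g, g) for g in ordering.order
        ],
        "relative_position": rel,
    }
    df = pd.DataFrame(rows)
    if stats is not None:
        if len(stats) != n:
            raise ValidationError("stats table length differs from ordering length")
        df = pd.concat([df, stats.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ordering(path) -> GeneOrdering:
    """Read an ordering TSV written by :func:`write_ordering`.

    Positions must be 1..N consecutive; relative positions are
    recomputed from the positions, never trusted from the file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "protein_id": str})
    for col in ("position", "gene"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    positions = df["position"].to_numpy()
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(positions, expected):
        bad = int(np.nonzero(positions != expected)[0][0])
        raise ValidationError(
            f"{path}: positions not consecutive 1..N (row {bad + 2}: "
            f"found {positions[bad]}, expected {expected[bad]})"
        )
    return GeneOrdering(df["gene"].tolist())
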
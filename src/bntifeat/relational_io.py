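"""Trees, distance matrices and community tables.

Everything downstream of this module works on three objects: a rooted
:class:`Dendrogram` over feature tips (a phylogeny for taxa, or a molecular
characteristics dendrogram for formulas), the symmetric tip-to-tip
:class:`DistanceMatrix` derived from it, and a sample x feature
:class:`CommunityTable` carrying an explicit abundance mode.  The label
shuffle used by every null model lives here as well: permuting the labels of
the cophenetic matrix is exactly equivalent to shuffling the tips of the
dendrogram, and avoids re-traversing the tree per null replicate.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

log = logging.getLogger("bntifeat")

__all__ = [
    "Dendrogram",
    "DistanceMatrix",
    "CommunityTable",
    "TaxonomyMap",
    "read_newick",
    "cophenetic_matrix",
    "shuffle_labels",
    "read_community_table",
    "read_taxonomy",
    "harmonize",
    "to_relative",
]

RANKS = ("Domain", "Phylum", "Class", "Order", "Family", "Genus")


class ValidationError(ValueError):
    """Input violates a structural invariant (bad tree, table, or matrix)."""


# ---------------------------------------------------------------------------
# Dendrogram


class Dendrogram:
    """Rooted tree with nonnegative branch lengths over unique feature tips.

    Thin validated wrapper around a ``skbio.TreeNode``.  Branch lengths of
    exactly 0 are allowed (polytomy-resolution artifacts); negative or
    non-finite lengths are rejected; a missing length is treated as 0.
    """

    def __init__(self, tree: TreeNode):
        tips = [t.name for t in tree.tips()]
        if len(tips) < 2:
            raise ValidationError(f"tree needs >= 2 tips, got {len(tips)}")
        if any(t is None for t in tips):
            raise ValidationError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for node in tree.traverse(include_self=True):
            if node.length is None:
                node.length = 0.0
            if not np.isfinite(node.length) or node.length < 0:
                raise ValidationError(
                    f"branch length {node.length!r} at node {node.name!r} "
                    "must be finite and >= 0"
                )
        self._tree = tree
        self.tips: tuple[str, ...] = tuple(tips)

    @property
    def tree(self) -> TreeNode:
        return self._tree

    def cophenetic(self) -> "DistanceMatrix":
        return cophenetic_matrix(self)

    def write(self, path) -> None:
        self._tree.write(str(path), format="newick")

    def to_newick(self) -> str:
        buf = io.StringIO()
        self._tree.write(buf, format="newick")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Dendrogram(n_tips={len(self.tips)})"


def read_newick(path) -> Dendrogram:
    """Read a newick file into a validated :class:`Dendrogram`."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises NewickFormatError with position
        raise ValidationError(f"malformed newick in {path}: {exc}") from exc
    return Dendrogram(tree)


def parse_newick(text: str) -> Dendrogram:
    """Parse a newick string (convenience entry used by generators/tests)."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:
        raise ValidationError(f"malformed newick: {exc}") from exc
    return Dendrogram(tree)


# ---------------------------------------------------------------------------
# DistanceMatrix


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal, labelled matrix of relational distances."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("distance matrix labels must be unique")
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.all(np.isfinite(v)):
            raise ValidationError("distances must be finite")
        if np.any(v < 0):
            raise ValidationError("distances must be >= 0")
        if not np.allclose(v, v.T, rtol=0, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValidationError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Restrict/reorder to ``labels`` (all must be present)."""
        idx = self.index()
        missing = [l for l in labels if l not in idx]
        if missing:
            raise ValidationError(f"labels not in matrix: {missing[:5]}")
        sel = np.array([idx[l] for l in labels])
        return DistanceMatrix(tuple(labels), self.values[np.ix_(sel, sel)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def cophenetic_matrix(tree: Dendrogram) -> DistanceMatrix:
    """Tip-to-tip path-length distances (cophenetic distances) of a tree."""
    dm = tree.tree.tip_tip_distances()
    # align to the Dendrogram's own tip order
    order = [dm.index(t) for t in tree.tips]
    vals = dm.data[np.ix_(order, order)]
    # guard against negative round-off from skbio accumulation
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(tree.tips, vals)


def shuffle_labels(D: DistanceMatrix, seed) -> DistanceMatrix:
    """Uniformly permute matrix labels (tip shuffle of the dendrogram).

    Equivalent to jointly permuting rows and columns: the multiset of
    off-diagonal distances is unchanged and the diagonal stays zero.
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(D.n)
    return DistanceMatrix(D.labels, D.values[np.ix_(perm, perm)])


# ---------------------------------------------------------------------------
# CommunityTable

MODES = ("counts", "relative", "presence")


@dataclass
class CommunityTable:
    """Sample x feature abundance table with an explicit abundance mode.

    ``data`` is samples-as-rows.  ``mode`` is one of ``counts`` (arbitrary
    nonnegative abundances), ``relative`` (rows sum to 1) or ``presence``
    (0/1 indicators).
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("table values must be finite")
        if np.any(vals < 0):
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValidationError("sample and feature identifiers must be unique")
        if self.mode == "presence" and not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValidationError("presence table must contain only 0/1")
        if self.mode == "relative":
            sums = vals.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
                raise ValidationError(f"relative rows must sum to 1 (sample {bad!r})")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def presence(self) -> np.ndarray:
        return self.values() > 0


def _infer_mode(vals: np.ndarray) -> str:
    if np.all(np.isin(vals, (0.0, 1.0))):
        return "presence"
    if np.allclose(vals.sum(axis=1), 1.0, rtol=0, atol=1e-6):
        return "relative"
    return "counts"


def read_community_table(path, mode_hint: str | None = None,
                         samples_as_rows: bool = True) -> CommunityTable:
    """Read a delimited sample x feature table.

    The delimiter follows the extension (``.csv`` -> comma, otherwise tab);
    the first column holds identifiers.  Orientation is declared, never
    guessed from shape.  With no ``mode_hint`` the mode is inferred (all
    values in {0,1} -> presence; rows summing to 1 -> relative; else counts)
    and the inference is logged.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any() and not df[col].isna().any():
                row = df.index[bad.isna().argmax()]
                raise ValidationError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                ) from exc
        raise ValidationError(f"non-numeric cells in {path}: {exc}") from exc
    if not samples_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    mode = mode_hint or _infer_mode(df.to_numpy(dtype=float))
    if mode_hint is None:
        log.info("inferred abundance mode %r for %s", mode, path)
    return CommunityTable(df, mode)


# ---------------------------------------------------------------------------
# TaxonomyMap


@dataclass
class TaxonomyMap:
    """feature id -> ranked lineage (Domain..Genus, missing ranks empty)."""

    data: pd.DataFrame  # index: feature_id, columns: RANKS

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValidationError("taxonomy feature ids must be unique")
        for r in RANKS:
            if r not in self.data.columns:
                self.data[r] = ""
        self.data = self.data[list(RANKS)].fillna("").astype(str)

    def lineage(self, feature: str) -> dict[str, str]:
        if feature not in self.data.index:
            return {r: "" for r in RANKS}
        return self.data.loc[feature].to_dict()


def read_taxonomy(path) -> TaxonomyMap:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyMap(df)


# ---------------------------------------------------------------------------
# harmonize / to_relative


def harmonize(table: CommunityTable, D: DistanceMatrix,
              prune: bool = False) -> tuple[CommunityTable, DistanceMatrix]:
    """Align the feature sets of a table and a distance matrix.

    With ``prune=False`` the feature sets must already be identical (order
    may differ).  With ``prune=True`` both objects are restricted to the
    intersection; samples left empty by pruning are removed with a warning.
    """
    tf, mf = set(table.features), set(D.labels)
    common = [f for f in table.features if f in mf]
    if not common:
        raise ValidationError("no features shared between table and matrix")
    if not prune and (tf != mf):
        raise ValidationError(
            f"feature sets differ (table-only: {len(tf - mf)}, "
            f"matrix-only: {len(mf - tf)}); pass prune=True to intersect"
        )
    dropped_t, dropped_m = len(tf - mf), len(mf - tf)
    if dropped_t or dropped_m:
        log.warning("harmonize dropped %d table feature(s) and %d matrix label(s)",
                    dropped_t, dropped_m)
    df = table.data[common]
    empty = df.sum(axis=1) == 0
    if empty.any():
        log.warning("harmonize removed %d sample(s) left empty by pruning: %s",
                    int(empty.sum()), list(df.index[empty]))
        df = df.loc[~empty]
        if df.shape[0] == 0:
            raise ValidationError("all samples empty after pruning")
    mode = table.mode
    if mode == "relative" and dropped_t:
        mode = "counts"  # row sums no longer 1; renormalise downstream
    return CommunityTable(df, mode), D.reorder(common)


def to_relative(table: CommunityTable) -> CommunityTable:
    """Normalise each sample row to sum to 1 (mode becomes ``relative``).

    Counts are divided by per-sample totals; presence rows by per-sample
    occupancy; relative tables pass through unchanged.
    """
    if table.mode == "relative":
        return table
    vals = table.values()
    sums = vals.sum(axis=1)
    if np.any(sums == 0):
        bad = table.data.index[int(np.argmax(sums == 0))]
        raise ValidationError(f"sample {bad!r} has all-zero abundances")
    df = pd.DataFrame(vals / sums[:, None], index=table.data.index,
                      columns=table.data.columns)
    return CommunityTable(df, "relative")
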
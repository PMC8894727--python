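"""Molecular formulas: parsing, derived properties, compound classes, and
the molecular characteristics dendrogram (MCD).

An assigned molecular formula (C/H/O/N/S/P counts, optionally a neutral
monoisotopic mass) yields a set of standard derived properties:

* DBE, double-bond equivalents: ``1 + (2C - H + N + P) / 2`` — rings plus
  pi bonds.
* AI_mod, modified aromaticity index:
  ``(1 + C - O/2 - S - (N + P + H)/2) / (C - O/2 - N - S - P)``, clamped to
  0 when the numerator is negative or the denominator nonpositive (the
  conventional treatment; without it heteroatom-rich formulas produce
  meaningless negative aromaticities).
* NOSC, nominal oxidation state of carbon:
  ``4 - (4C + H - 3N - 2O + 5P - 2S) / C`` — equivalent to assigning
  H +1, O -2, N -3, S -2, P +5 in a neutral molecule.
* Kendrick mass ``mass * 14 / 14.01565`` and Kendrick defect
  ``round(KM) - KM`` (members of a CH2 homologous series share a defect);
  a ``floor`` convention is available.

Van Krevelen compound classes are assigned from rectangular O/C-H/C
boundaries shipped as an editable TSV (first matching row wins).  The MCD
standardises a chosen property set, takes Euclidean distances and UPGMA
agglomeration, and emits an ultrametric dendrogram whose cophenetic
distances are the merge heights — the organic-matter analogue of a
phylogeny for the feature-level metric.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from skbio import TreeNode

from .relational_io import Dendrogram, ValidationError

log = logging.getLogger("bntifeat")

__all__ = [
    "FormulaRecord",
    "parse_formula",
    "derived_properties",
    "load_class_boundaries",
    "compound_class",
    "assign_classes",
    "build_mcd",
    "read_formula_table",
    "formulas_to_frame",
    "DEFAULT_MCD_PROPERTIES",
]

ELEMENTS = ("C", "H", "O", "N", "S", "P")
CH2 = 14.01565
DEFAULT_MCD_PROPERTIES = ("c", "h", "o", "n", "s", "p", "oc_ratio",
                          "hc_ratio", "dbe", "ai_mod", "nosc",
                          "kendrick_defect")


@dataclass
class FormulaRecord:
    """One molecular formula with element counts and derived properties."""

    feature_id: str
    c: int
    h: int
    o: int = 0
    n: int = 0
    s: int = 0
    p: int = 0
    mass: float | None = None
    dbe: float = field(default=math.nan)
    ai_mod: float = field(default=math.nan)
    nosc: float = field(default=math.nan)
    kendrick_mass: float = field(default=math.nan)
    kendrick_defect: float = field(default=math.nan)
    oc_ratio: float = field(default=math.nan)
    hc_ratio: float = field(default=math.nan)
    elemental_group: str = ""
    compound_class: str = ""

    def __post_init__(self):
        if self.c < 1:
            raise ValidationError(f"{self.feature_id}: formulas need C >= 1")
        for el in ELEMENTS:
            if getattr(self, el.lower()) < 0:
                raise ValidationError(f"{self.feature_id}: negative {el} count")
        self.elemental_group = "".join(
            el for el in ELEMENTS if getattr(self, el.lower()) > 0)

    def counts(self) -> dict[str, int]:
        return {el: getattr(self, el.lower()) for el in ELEMENTS}


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str, feature_id: str | None = None) -> FormulaRecord:
    """Parse a molecular formula string such as ``C47H68O10`` or ``C34H63O4P``.

    Only C, H, O, N, S, P are accepted; an omitted count means 1; a repeated
    element is an error.
    """
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ValidationError(
                f"cannot parse formula {text!r} at offset {pos}")
        el, num = m.group(1), m.group(2)
        if el not in ELEMENTS:
            raise ValidationError(f"unknown element {el!r} in formula {text!r}")
        if el in counts:
            raise ValidationError(f"repeated element {el!r} in formula {text!r}")
        counts[el] = int(num) if num else 1
        pos = m.end()
    if pos != len(text) or not counts:
        raise ValidationError(f"cannot parse formula {text!r} at offset {pos}")
    return FormulaRecord(feature_id or text,
                         **{el.lower(): counts.get(el, 0) for el in ELEMENTS})


def derived_properties(rec: FormulaRecord,
                       kendrick_convention: str = "round") -> FormulaRecord:
    """Fill in DBE, AI_mod, NOSC, O/C, H/C and (mass permitting) the
    Kendrick mass and defect.  Returns the same record, mutated."""
    c, h, o, n, s, p = rec.c, rec.h, rec.o, rec.n, rec.s, rec.p
    rec.dbe = 1.0 + (2 * c - h + n + p) / 2.0
    num = 1.0 + c - o / 2.0 - s - (n + p + h) / 2.0
    den = c - o / 2.0 - n - s - p
    rec.ai_mod = 0.0 if (num < 0 or den <= 0) else num / den
    rec.nosc = 4.0 - (4 * c + h - 3 * n - 2 * o + 5 * p - 2 * s) / c
    rec.oc_ratio = o / c
    rec.hc_ratio = h / c
    if rec.mass is not None and np.isfinite(rec.mass):
        km = rec.mass * 14.0 / CH2
        rec.kendrick_mass = km
        anchor = round(km) if kendrick_convention == "round" else math.floor(km)
        rec.kendrick_defect = anchor - km
    else:
        rec.kendrick_mass = math.nan
        rec.kendrick_defect = math.nan
        log.debug("%s: no mass; Kendrick fields undefined", rec.feature_id)
    return rec


# ---------------------------------------------------------------------------
# compound classes


def load_class_boundaries(path=None) -> pd.DataFrame:
    """Load a class-boundary table (columns class, oc_min, oc_max, hc_min,
    hc_max).  With no path, the packaged default Van Krevelen set is used."""
    if path is None:
        ref = importlib.resources.files("bntifeat").joinpath(
            "data/compound_classes.tsv")
        with importlib.resources.as_file(ref) as f:
            df = pd.read_csv(f, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    need = {"class", "oc_min", "oc_max", "hc_min", "hc_max"}
    if not need.issubset(df.columns):
        raise ValidationError(
            f"class boundary table must have columns {sorted(need)}")
    for col in ("oc_min", "oc_max", "hc_min", "hc_max"):
        df[col] = df[col].astype(float)
    if (df["oc_min"] > df["oc_max"]).any() or (df["hc_min"] > df["hc_max"]).any():
        raise ValidationError("class boundary mins exceed maxes")
    _warn_overlaps(df)
    return df


def _warn_overlaps(df: pd.DataFrame) -> None:
    rows = df.to_dict("records")
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            if (a["oc_min"] <= b["oc_max"] and b["oc_min"] <= a["oc_max"]
                    and a["hc_min"] <= b["hc_max"] and b["hc_min"] <= a["hc_max"]):
                log.warning("compound-class boundaries overlap: %r and %r "
                            "(first in table order wins)",
                            a["class"], b["class"])


def compound_class(rec: FormulaRecord, boundaries: pd.DataFrame) -> str:
    """First class whose O/C-H/C rectangle contains the formula; ``Other``
    when none matches (shared edges go to the earlier row)."""
    oc, hc = rec.oc_ratio, rec.hc_ratio
    if not (np.isfinite(oc) and np.isfinite(hc)):
        raise ValidationError(
            f"{rec.feature_id}: derive properties before class assignment")
    for row in boundaries.to_dict("records"):
        if (row["oc_min"] <= oc <= row["oc_max"]
                and row["hc_min"] <= hc <= row["hc_max"]):
            return str(row["class"])
    return "Other"


def assign_classes(records: list[FormulaRecord],
                   boundaries: pd.DataFrame | None = None) -> list[FormulaRecord]:
    boundaries = boundaries if boundaries is not None else load_class_boundaries()
    for rec in records:
        rec.compound_class = compound_class(rec, boundaries)
    return records


# ---------------------------------------------------------------------------
# molecular characteristics dendrogram


def build_mcd(records: list[FormulaRecord],
              properties: tuple[str, ...] | None = None,
              linkage_method: str = "upgma") -> Dendrogram:
    """Build the molecular characteristics dendrogram (MCD).

    Each selected property is standardised to zero mean and unit variance
    (constant or undefined properties are dropped with a warning), pairwise
    Euclidean distances are clustered by UPGMA, and the result is returned
    as a dendrogram whose cophenetic distances equal the merge heights.
    Deterministic given the input order.
    """
    if linkage_method != "upgma":
        raise ValidationError("only UPGMA linkage is supported")
    if len(records) < 2:
        raise ValidationError("MCD needs at least 2 formula records")
    props = tuple(properties) if properties else DEFAULT_MCD_PROPERTIES
    cols = []
    kept = []
    for pname in props:
        try:
            col = np.array([float(getattr(r, pname)) for r in records])
        except AttributeError as exc:
            raise ValidationError(f"unknown property {pname!r}") from exc
        if not np.all(np.isfinite(col)):
            log.warning("MCD property %r undefined for some records; dropped",
                        pname)
            continue
        sd = col.std()
        if sd == 0:
            log.warning("MCD property %r is constant; dropped", pname)
            continue
        cols.append((col - col.mean()) / sd)
        kept.append(pname)
    if not cols:
        raise ValidationError("no usable (finite, non-constant) MCD properties")
    X = np.column_stack(cols)
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    ids = [r.feature_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("formula feature ids must be unique")
    return Dendrogram(_linkage_to_tree(Z, ids))


def _linkage_to_tree(Z: np.ndarray, labels: list[str]) -> TreeNode:
    """Convert a scipy linkage into an ultrametric skbio tree whose
    tip-to-tip distances equal the merge heights (child branch length =
    (parent height - child height) / 2)."""
    root, nodes = to_tree(Z, rd=True)

    def build(node) -> TreeNode:
        if node.is_leaf():
            return TreeNode(name=labels[node.id], length=node.dist / 2.0)
        children = [build(node.left), build(node.right)]
        for ch, sub in zip(children, (node.left, node.right)):
            ch.length = (node.dist - sub.dist) / 2.0
        t = TreeNode(children=children)
        return t

    tree = build(root)
    tree.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# table I/O


def read_formula_table(path, kendrick_convention: str = "round") -> list[FormulaRecord]:
    """Read a formula table (feature_id plus either a ``formula`` column or
    per-element C,H,O,N,S,P columns; optional ``mass``) and derive
    properties."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "feature_id" not in df.columns:
        raise ValidationError("formula table needs a feature_id column")
    records = []
    for _, row in df.iterrows():
        fid = str(row["feature_id"])
        if "formula" in df.columns and isinstance(row.get("formula"), str):
            rec = parse_formula(row["formula"], feature_id=fid)
        else:
            colmap = {el: (el if el in df.columns else el.lower())
                      for el in ELEMENTS}
            missing = [el for el, c in colmap.items() if c not in df.columns]
            if missing:
                raise ValidationError(
                    f"formula table needs a formula column or element columns; "
                    f"missing {missing}")
            rec = FormulaRecord(fid, **{el.lower(): int(row[colmap[el]])
                                        for el in ELEMENTS})
        if "mass" in df.columns and pd.notna(row.get("mass")):
            rec.mass = float(row["mass"])
        derived_properties(rec, kendrick_convention)
        records.append(rec)
    return records


def formulas_to_frame(records: list[FormulaRecord]) -> pd.DataFrame:
    cols = ["feature_id", "c", "h", "o", "n", "s", "p", "mass", "dbe",
            "ai_mod", "nosc", "kendrick_mass", "kendrick_defect", "oc_ratio",
            "hc_ratio", "elemental_group", "compound_class"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
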
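"""Co-contribution networks over feature-level z-score profiles.

Pairwise-mode z-score profiles (features x partner samples) from one or two
feature types (taxa, formulas) are correlated feature-by-feature; a signed
soft-threshold adjacency and average-linkage clustering yield modules of
features whose contributions to convergence/divergence rise and fall
together.  This is a deliberately simplified weighted-correlation-network
procedure (no topological overlap matrix, no dynamic tree cut); parameters
are explicit and recorded with the output.  Modules smaller than
``min_size`` (default 3) are dissolved to unassigned, which removes
doublets — isolated mutually-correlated pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .feature_bnti import ContributionCategory
from .formulas import FormulaRecord
from .relational_io import CommunityTable, TaxonomyMap, ValidationError
from .summaries import ProfileMatrix

log = logging.getLogger("bntifeat")

__all__ = [
    "ModuleAssignment",
    "ModuleStats",
    "correlate_profiles",
    "detect_modules",
    "module_stats",
    "export_network",
]


@dataclass(frozen=True)
class ModuleAssignment:
    feature: str
    feature_type: str          # "taxon" | "formula"
    module_id: int | None      # None = unassigned (dissolved)
    module_label: str


@dataclass
class ModuleStats:
    module_id: int
    size: int
    n_taxa: int
    n_formulas: int
    shannon_h: float
    exp_h: float
    pielou_j: float
    n_orders: int
    elemental_composition_proportions: dict[str, float]


def correlate_profiles(P1: ProfileMatrix, P2: ProfileMatrix | None = None
                       ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pearson correlations between every pair of z-score profiles.

    Profiles must share the same partner samples in the same order; features
    with any missing entry are excluded (logged; missing z-values are
    information, imputation is refused), as are zero-variance profiles.
    Returns the correlation matrix and a feature -> type map (types are
    ``taxon`` for P1 and ``formula`` for P2; with a single input every
    feature is ``taxon``).
    """
    blocks = [("taxon", P1)] + ([("formula", P2)] if P2 is not None else [])
    if P2 is not None and P1.partners != P2.partners:
        raise ValidationError(
            "profiles must share identical partner samples and ordering")
    if len(P1.partners) < 3:
        raise ValidationError("need >= 3 shared partner samples to correlate")
    rows, names, types = [], [], {}
    for ftype, prof in blocks:
        X = prof.data.to_numpy(dtype=float)
        complete = ~np.isnan(X).any(axis=1)
        n_drop = int((~complete).sum())
        if n_drop:
            log.info("dropped %d %s profile(s) with missing entries",
                     n_drop, ftype)
        for i in np.flatnonzero(complete):
            x = X[i]
            if x.std() == 0:
                log.warning("feature %r has a zero-variance profile; excluded",
                            prof.data.index[i])
                continue
            rows.append(x)
            names.append(prof.data.index[i])
            types[prof.data.index[i]] = ftype
    if len(rows) < 2:
        raise ValidationError("fewer than 2 usable profiles")
    if len(set(names)) != len(names):
        raise ValidationError("feature ids must be unique across profiles")
    C = np.corrcoef(np.vstack(rows))
    C = np.clip(C, -1.0, 1.0)
    return pd.DataFrame(C, index=names, columns=names), types


def detect_modules(C: pd.DataFrame, feature_types: dict[str, str] | None = None,
                   power: float = 6.0, cut_height: float = 0.25,
                   min_size: int = 3, signed: bool = True
                   ) -> list[ModuleAssignment]:
    """Soft-threshold the correlations and cut an average-linkage tree.

    Signed adjacency ``((1 + r) / 2) ** power`` (or ``|r| ** power``
    unsigned), dissimilarity ``1 - a``, flat modules at ``cut_height``;
    modules smaller than ``min_size`` are dissolved to unassigned (the
    doublet filter).
    """
    vals = C.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1] or not np.allclose(vals, vals.T,
                                                         atol=1e-10):
        raise ValidationError("correlation matrix must be square symmetric")
    if power <= 0 or not (0 < cut_height < 1):
        raise ValidationError("need power > 0 and cut_height in (0, 1)")
    a = ((1 + vals) / 2.0) ** power if signed else np.abs(vals) ** power
    dis = 1.0 - a
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2, 0, None)
    if np.allclose(dis, 0):
        log.warning("degenerate correlation matrix: all features identical; "
                    "a single module is returned")
        flat = np.ones(len(C), dtype=int)
    else:
        Z = linkage(squareform(dis, checks=False), method="average")
        flat = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(flat).value_counts()
    keep = sorted([cid for cid, n in sizes.items() if n >= min_size],
                  key=lambda cid: (-sizes[cid], cid))
    relabel = {cid: k + 1 for k, cid in enumerate(keep)}
    types = feature_types or {}
    out = []
    for feat, cid in zip(C.index, flat):
        mid = relabel.get(cid)
        out.append(ModuleAssignment(
            feature=str(feat),
            feature_type=types.get(str(feat), "taxon"),
            module_id=mid,
            module_label=f"M{mid}" if mid is not None else "unassigned"))
    n_diss = sum(1 for m in out if m.module_id is None)
    if n_diss:
        log.info("dissolved %d feature(s) in modules smaller than %d",
                 n_diss, min_size)
    return out


def module_stats(assignments: list[ModuleAssignment],
                 table: CommunityTable | None = None,
                 taxonomy: TaxonomyMap | None = None,
                 formulas: list[FormulaRecord] | None = None
                 ) -> list[ModuleStats]:
    """Diversity and composition statistics per module.

    Shannon H is computed over the member taxa's mean relative abundances
    (renormalised within the module), exp(H) is its effective species
    number, Pielou J = H / ln(richness) (undefined for richness 1),
    n_orders counts distinct taxonomic Orders, and elemental-composition
    proportions are over the module's formula members.  A module without
    taxa gets NaN taxon metrics, never zero.
    """
    frec = {r.feature_id: r for r in (formulas or [])}
    mean_ab: dict[str, float] = {}
    if table is not None:
        from .relational_io import to_relative
        rel = to_relative(table)
        mean_ab = rel.data.mean(axis=0).to_dict()
    mods: dict[int, list[ModuleAssignment]] = {}
    for a in assignments:
        if a.module_id is not None:
            mods.setdefault(a.module_id, []).append(a)
    out = []
    for mid in sorted(mods):
        members = mods[mid]
        taxa = [m.feature for m in members if m.feature_type == "taxon"]
        forms = [m.feature for m in members if m.feature_type == "formula"]
        h = exph = j = math.nan
        n_orders = 0
        if taxa and table is not None:
            p = np.array([mean_ab.get(t, 0.0) for t in taxa])
            if p.sum() > 0:
                p = p[p > 0] / p[p > 0].sum()
                h = float(-(p * np.log(p)).sum())
                exph = float(np.exp(h))
                j = h / math.log(len(p)) if len(p) > 1 else math.nan
        if taxa and taxonomy is not None:
            orders = {taxonomy.lineage(t).get("Order", "") for t in taxa}
            n_orders = len({o for o in orders if o})
        props: dict[str, float] = {}
        groups = [frec[f].elemental_group for f in forms if f in frec]
        if groups:
            ser = pd.Series(groups).value_counts(normalize=True)
            props = {k: float(v) for k, v in ser.items()}
        out.append(ModuleStats(
            module_id=mid, size=len(members), n_taxa=len(taxa),
            n_formulas=len(forms), shannon_h=h, exp_h=exph, pielou_j=j,
            n_orders=n_orders, elemental_composition_proportions=props))
    return out


def export_network(C: pd.DataFrame, assignments: list[ModuleAssignment],
                   threshold: float = 0.6
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list (|r| >= threshold) and node-attribute table for graph
    viewers."""
    amap = {a.feature: a for a in assignments}
    feats = [str(f) for f in C.index]
    vals = C.to_numpy(dtype=float)
    edges = []
    for i in range(len(feats)):
        for jj in range(i + 1, len(feats)):
            r = vals[i, jj]
            if abs(r) >= threshold:
                edges.append({"source": feats[i], "target": feats[jj],
                              "weight": float(r),
                              "sign": "positive" if r >= 0 else "negative"})
    nodes = [{"feature": f,
              "type": amap[f].feature_type if f in amap else "",
              "module": amap[f].module_label if f in amap else ""}
             for f in feats]
    return pd.DataFrame(edges, columns=["source", "target", "weight", "sign"]), \
        pd.DataFrame(nodes, columns=["feature", "type", "module"])
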
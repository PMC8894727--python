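"""Descriptive layers over feature-level z-scores: cross-dataset preference
labels, taxonomy-level aggregation, contribution-frequency tables, and
pairwise-to-focal temporal profiles."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_bnti import ContributionCategory, FeatureAssemblyRecord
from .relational_io import RANKS, TaxonomyMap, ValidationError

log = logging.getLogger("bntifeat")

__all__ = [
    "PreferenceLabel",
    "ProfileMatrix",
    "compare_datasets",
    "aggregate_by_rank",
    "contribution_frequency",
    "temporal_profile",
]

PREFERENCE_LABELS = ("A_favored", "B_favored", "Neither", "A_only", "B_only")


@dataclass(frozen=True)
class PreferenceLabel:
    feature: str
    label: str


@dataclass
class ProfileMatrix:
    """Features x partner-samples matrix of z-scores from pairwise mode
    against a fixed focal sample; missing cells stay NaN (Absent/Undefined
    is information, not zero)."""

    data: pd.DataFrame
    focal: str

    @property
    def partners(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.data.index)


def _z_by_feature(records: Iterable[FeatureAssemblyRecord]) -> dict[str, float]:
    out: dict[str, float] = {}
    for r in records:
        if r.feature in out:
            raise ValidationError(
                f"duplicate feature {r.feature!r} within a run")
        out[r.feature] = r.bnti
    return out


def compare_datasets(recA: Sequence[FeatureAssemblyRecord],
                     recB: Sequence[FeatureAssemblyRecord],
                     tol: float = 1e-6) -> list[PreferenceLabel]:
    """Which dataset each feature contributes to more strongly.

    A feature present in both runs is ``A_favored`` when |z_A| - |z_B| > tol,
    ``B_favored`` when < -tol, else ``Neither``; a feature with a usable z in
    only one run gets ``A_only``/``B_only``.  Features with undefined or
    absent z on a side are treated as missing from that side.
    """
    zA, zB = _z_by_feature(recA), _z_by_feature(recB)

    def usable(z):
        return z is not None and not math.isnan(z)

    labels = []
    for f in sorted(set(zA) | set(zB)):
        a_ok = f in zA and usable(zA[f])
        b_ok = f in zB and usable(zB[f])
        if a_ok and b_ok:
            diff = abs(zA[f]) - abs(zB[f])
            lab = ("A_favored" if diff > tol
                   else "B_favored" if diff < -tol else "Neither")
        elif a_ok:
            lab = "A_only"
        elif b_ok:
            lab = "B_only"
        else:
            continue
        labels.append(PreferenceLabel(f, lab))
    return labels


def aggregate_by_rank(records: Sequence[FeatureAssemblyRecord],
                      taxonomy: TaxonomyMap, rank: str) -> pd.DataFrame:
    """Summarise z-scores per taxonomic group at ``rank``.

    Unmapped/unassigned features fall into ``Unclassified <parent>`` where
    parent is the nearest assigned higher rank.  Reports member count, mean
    and median z (both, because bimodal groups make the mean misleading),
    the share of each contribution category, and mean-based contribution
    flags (|mean z| > 1 contributes, > 2 significant).
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; choose from {RANKS}")
    rows = []
    for r in records:
        lin = taxonomy.lineage(r.feature)
        name = lin.get(rank, "")
        if not name:
            parent = ""
            for higher in RANKS[:RANKS.index(rank)][::-1]:
                if lin.get(higher, ""):
                    parent = lin[higher]
                    break
            name = f"Unclassified {parent}".strip()
        rows.append({"group": name, "bnti": r.bnti,
                     "category": r.category.value})
    df = pd.DataFrame(rows)
    out = []
    for g, sub in df.groupby("group", sort=True):
        z = sub["bnti"].to_numpy()
        zdef = z[np.isfinite(z)]
        mean = float(zdef.mean()) if zdef.size else math.nan
        rec = {
            "group": g,
            "n_features": len(sub),
            "mean_bnti": mean,
            "median_bnti": float(np.median(zdef)) if zdef.size else math.nan,
            # boundary values belong to the higher-magnitude category,
            # matching the per-feature classification convention
            "mean_contributes": bool(abs(mean) >= 1) if zdef.size else False,
            "mean_significant": bool(abs(mean) >= 2) if zdef.size else False,
        }
        for cat in ContributionCategory:
            rec[f"share_{cat.value}"] = float(
                (sub["category"] == cat.value).mean())
        out.append(rec)
    return pd.DataFrame(out)


def contribution_frequency(records: Sequence[FeatureAssemblyRecord],
                           grouping: Mapping[str, str] | Callable[[str], str]
                           ) -> pd.DataFrame:
    """Per group, the proportion of features in each contribution category
    (rows sum to 1).  ``grouping`` maps feature id -> group label (e.g.
    elemental composition group or compound class); empty groups are
    omitted with a warning."""
    getg = grouping if callable(grouping) else grouping.__getitem__
    rows = []
    for r in records:
        try:
            g = getg(r.feature)
        except KeyError as exc:
            raise ValidationError(
                f"feature {r.feature!r} has no group") from exc
        rows.append({"group": g, "category": r.category.value})
    df = pd.DataFrame(rows)
    if not callable(grouping):
        unused = set(grouping.values()) - set(df["group"])
        for g in sorted(unused):
            log.warning("group %r has no features; omitted", g)
    out = []
    for g, sub in df.groupby("group", sort=True):
        rec = {"group": g, "n_features": len(sub)}
        for cat in ContributionCategory:
            rec[f"prop_{cat.value}"] = float(
                (sub["category"] == cat.value).mean())
        out.append(rec)
    return pd.DataFrame(out)


def temporal_profile(records: Sequence[FeatureAssemblyRecord], focal: str,
                     sample_order: Sequence[str]) -> ProfileMatrix:
    """Features x ordered-partner matrix of z-scores from pairwise records
    with the given focal sample; Absent/Undefined entries are NaN."""
    expect = f"focal={focal}"
    partners = [s for s in sample_order if s != focal]
    cells: dict[tuple[str, str], float] = {}
    feats: list[str] = []
    for r in records:
        if r.partner is None or r.scope_label != expect:
            raise ValidationError(
                "temporal_profile needs pairwise records with focal "
                f"{focal!r} (got scope {r.scope_label!r})")
        if r.feature not in feats:
            feats.append(r.feature)
        cells[(r.feature, r.partner)] = r.bnti
    data = pd.DataFrame(
        [[cells.get((f, p), math.nan) for p in partners] for f in feats],
        index=feats, columns=partners, dtype=float)
    return ProfileMatrix(data, focal)
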
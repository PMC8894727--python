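"""Whole-community distances: beta-MNTD, community-level z-scores, and
taxonomic dissimilarities (Bray-Curtis, Jaccard).

These are the standard companions of the feature-level metric: beta-MNTD is
the abundance-weighted mean distance from each feature in one sample to its
nearest relative in the other, and the community z-score compares it against
the same shared tip-shuffle null (without noise injection).  The square
matrices produced here are what ordination/PERMANOVA libraries consume; no
ordination is done in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .feature_bnti import NullConfig, _ntd_matrix, _permutations
from .relational_io import (
    CommunityTable,
    DistanceMatrix,
    ValidationError,
    to_relative,
)

log = logging.getLogger("bntifeat")

__all__ = [
    "PairwiseMatrix",
    "community_bmntd",
    "community_bmntd_matrix",
    "community_bnti",
    "community_bnti_matrix",
    "taxonomic_dissimilarity",
]


@dataclass(frozen=True)
class PairwiseMatrix:
    """Labelled square matrix of a pairwise sample metric."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def pair(self, i: str, j: str) -> float:
        a, b = self.labels.index(i), self.labels.index(j)
        return float(self.values[a, b])


def _check_nonempty(table: CommunityTable) -> None:
    sums = table.values().sum(axis=1)
    if np.any(sums == 0):
        bad = table.data.index[int(np.argmax(sums == 0))]
        raise ValidationError(f"sample {bad!r} is empty")


def _bmntd_values(R: np.ndarray, ntd: np.ndarray) -> np.ndarray:
    # B[i, j] = sum_a f_ai * ntd(a, j); bmntd = (B + B.T) / 2
    B = R @ np.nan_to_num(ntd, nan=0.0)
    return (B + B.T) / 2.0


def community_bmntd_matrix(table: CommunityTable, D: DistanceMatrix,
                           allow_conspecifics: bool = True) -> PairwiseMatrix:
    """Beta-mean nearest taxon distance between every pair of samples."""
    _check_nonempty(table)
    D = D.reorder(table.features)
    R = to_relative(table).values()
    ntd = _ntd_matrix(D.values, table.presence(), allow_conspecifics)
    vals = _bmntd_values(R, ntd)
    return PairwiseMatrix(table.samples, vals, "bmntd")


def community_bmntd(i: str, j: str, table: CommunityTable, D: DistanceMatrix,
                    allow_conspecifics: bool = True) -> float:
    """Beta-MNTD between two samples (abundance-weighted, both directions)."""
    return community_bmntd_matrix(table, D, allow_conspecifics).pair(i, j)


def community_bnti_matrix(table: CommunityTable, D: DistanceMatrix,
                          cfg: NullConfig | None = None) -> PairwiseMatrix:
    """Community-level z-scores of beta-MNTD against the tip-shuffle null.

    The null shares one label permutation per replicate across all sample
    pairs; no noise is injected, so identical-composition pairs (observed 0,
    null 0) come out NaN (undefined) and are logged.
    """
    cfg = cfg or NullConfig()
    _check_nonempty(table)
    D = D.reorder(table.features)
    R = to_relative(table).values()
    P = table.presence()
    obs = _bmntd_values(R, _ntd_matrix(D.values, P, cfg.allow_conspecifics))
    rng = np.random.default_rng(cfg.seed)
    perms = _permutations(D.n, cfg, rng)
    nulls = np.empty((len(perms),) + obs.shape)
    for r, perm in enumerate(perms):
        Dp = D.values[np.ix_(perm, perm)]
        nulls[r] = _bmntd_values(R, _ntd_matrix(Dp, P, cfg.allow_conspecifics))
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1) if len(perms) > 1 else np.full(obs.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    np.fill_diagonal(z, np.nan)
    n_undef = int(np.isnan(z[np.triu_indices_from(z, k=1)]).sum())
    if n_undef:
        log.warning("community z undefined (zero null SD) for %d sample pair(s)",
                    n_undef)
    return PairwiseMatrix(table.samples, z, "bnti")


def community_bnti(i: str, j: str, table: CommunityTable, D: DistanceMatrix,
                   cfg: NullConfig | None = None) -> float:
    return community_bnti_matrix(table, D, cfg).pair(i, j)


def taxonomic_dissimilarity(table: CommunityTable,
                            metric: str = "bray_curtis") -> PairwiseMatrix:
    """Bray-Curtis (on relative abundances) or Jaccard (on presence)."""
    _check_nonempty(table)
    if metric == "bray_curtis":
        R = to_relative(table).values()
        vals = squareform(pdist(R, metric="braycurtis"))
    elif metric == "jaccard":
        vals = squareform(pdist(table.presence(), metric="jaccard"))
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    return PairwiseMatrix(table.samples, vals, metric)
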
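"""Feature-level beta nearest taxon index (feature-level z-scores).

The metric asks, for each individual feature (a taxon or a molecular
formula), whether its nearest-relative distances across the communities of a
dataset are smaller or larger than expected when tip labels are shuffled at
random on the dendrogram.  The observed quantity is a feature-level
beta-mean nearest taxon distance,

    bmntd_feat(a, scope) = w_a * (1/n) * sum_j ntd(a, j)

where ``ntd(a, j)`` is the distance from feature ``a`` to its nearest
relative present in community ``j``, ``n`` is the number of communities in
the scope and ``w_a`` is the feature's (mean) relative abundance.  A null
distribution is obtained by recomputing the same quantity after jointly
permuting the labels of the cophenetic matrix (exactly a tip shuffle),
keeping abundances fixed, and the z-score

    bnti_feat = (obs - mean(null)) / sd(null)

is interpreted with the conventional thresholds: |z| < 1 insignificant,
1 <= |z| < 2 a contribution, |z| >= 2 a significant contribution;
negative z marks convergence, positive z divergence.

A vanishingly small noise term (uniform on [1e-20, 5e-20] by default) is
added to every null replicate so that features that are conspecific on both
sides of every comparison (all nearest distances exactly zero) still yield a
finite, if degenerate, z-score of about -2.6 rather than 0/0.  The noise is
below double-precision resolution relative to any nonzero distance, so it
changes nothing else.

Three scope modes are supported: ``dataset`` (one z per feature), ``group``
(one z per feature per group of samples, nulls drawn within the group) and
``pairwise`` (one z per feature per partner sample against a fixed focal
sample).  Within a null replicate a single shared label permutation is
applied to all features, partners and groups, so values are comparable
within a replicate.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .relational_io import (
    CommunityTable,
    DistanceMatrix,
    ValidationError,
    to_relative,
)

log = logging.getLogger("bntifeat")

__all__ = [
    "NullConfig",
    "Scope",
    "ContributionCategory",
    "FeatureAssemblyRecord",
    "classify",
    "nearest_taxon_distance",
    "feature_bmntd",
    "null_distribution",
    "feature_bnti",
    "run",
    "records_to_frame",
]


class ContributionCategory(str, Enum):
    SIG_CONVERGENCE = "SigConvergence"
    CONVERGENCE = "Convergence"
    INSIGNIFICANT = "Insignificant"
    DIVERGENCE = "Divergence"
    SIG_DIVERGENCE = "SigDivergence"
    UNDEFINED = "Undefined"
    ABSENT = "Absent"


@dataclass(frozen=True)
class NullConfig:
    """Null-model settings.

    ``n_null`` randomized communities (999 by default), each a tip shuffle of
    the dendrogram; ``noise_low``/``noise_high`` bound the uniform noise
    injected per replicate per feature; ``exhaustive`` enumerates every
    distinct tip permutation instead of sampling (only sensible for tiny
    trees, capped at ``exhaustive_cap`` tips) and then adds no noise.
    """

    n_null: int = 999
    noise_low: float = 1e-20
    noise_high: float = 5e-20
    seed: int = 0
    exhaustive: bool = False
    exhaustive_cap: int = 8
    allow_conspecifics: bool = True

    def __post_init__(self):
        if self.n_null < 1:
            raise ValidationError("n_null must be >= 1")
        if not (0 <= self.noise_low <= self.noise_high):
            raise ValidationError("need 0 <= noise_low <= noise_high")


@dataclass(frozen=True)
class Scope:
    """Which samples a feature-level value is computed over.

    ``mode`` is ``dataset``, ``group`` or ``pairwise``; ``samples`` the
    ordered subset of sample identifiers (n of the averaging); ``focal`` the
    fixed focal sample, required in pairwise mode.
    """

    mode: str
    samples: tuple[str, ...]
    focal: str | None = None
    label: str = ""

    def __post_init__(self):
        if self.mode not in ("dataset", "group", "pairwise"):
            raise ValidationError(f"unknown scope mode {self.mode!r}")
        if not self.samples:
            raise ValidationError("scope needs at least one sample")
        if self.mode == "pairwise":
            if self.focal is None:
                raise ValidationError("pairwise scope requires a focal sample")
            if self.focal not in self.samples:
                raise ValidationError("focal must be among the scope samples")
        if not self.label:
            object.__setattr__(
                self, "label",
                self.mode if self.mode != "pairwise" else f"focal={self.focal}")


@dataclass
class FeatureAssemblyRecord:
    feature: str
    scope_label: str
    partner: str | None
    abundance_weight: float
    bmntd_obs: float
    null_mean: float
    null_sd: float
    bnti: float
    category: ContributionCategory


def classify(z: float | None) -> ContributionCategory:
    """Map a z-score to its contribution category.

    Boundary values are assigned to the higher-magnitude category
    (|z| = 2 is significant, |z| = 1 contributes).
    """
    if z is None or (isinstance(z, float) and math.isnan(z)):
        return ContributionCategory.UNDEFINED
    az = abs(z)
    if az < 1:
        return ContributionCategory.INSIGNIFICANT
    if az < 2:
        return (ContributionCategory.CONVERGENCE if z < 0
                else ContributionCategory.DIVERGENCE)
    return (ContributionCategory.SIG_CONVERGENCE if z < 0
            else ContributionCategory.SIG_DIVERGENCE)


# ---------------------------------------------------------------------------
# nearest-taxon distances


def _ntd_matrix(Dv: np.ndarray, presence: np.ndarray,
                allow_conspecifics: bool) -> np.ndarray:
    """Distance of every feature to its nearest present feature per sample.

    ``Dv`` is the (F, F) distance matrix, ``presence`` an (S, F) boolean
    mask.  Returns an (F, S) array; NaN where a sample offers no comparator
    (empty sample, or only the feature itself with conspecifics excluded).
    """
    if not allow_conspecifics:
        Dv = Dv.copy()
        np.fill_diagonal(Dv, np.inf)
    n_feat = Dv.shape[0]
    n_samp = presence.shape[0]
    out = np.full((n_feat, n_samp), np.nan)
    for s in range(n_samp):
        idx = np.flatnonzero(presence[s])
        if idx.size:
            out[:, s] = Dv[:, idx].min(axis=1)
    out[np.isinf(out)] = np.nan
    return out


def nearest_taxon_distance(a: str, j: str, table: CommunityTable,
                           D: DistanceMatrix,
                           allow_conspecifics: bool = True) -> float:
    """Minimum distance from feature ``a`` to any feature present in ``j``.

    With conspecifics allowed and ``a`` itself present in ``j`` the result
    is 0.  NaN when ``j`` offers no comparator.
    """
    D = D.reorder(table.features)
    ai = table.features.index(a)
    si = table.samples.index(j)
    col = _ntd_matrix(D.values, table.presence()[si:si + 1],
                      allow_conspecifics)[ai, 0]
    return float(col)


# ---------------------------------------------------------------------------
# internal engine


@dataclass
class _ScopeJob:
    label: str
    sample_idx: np.ndarray          # rows of the table in the scope average
    focal_idx: int | None = None    # pairwise only; sample_idx are partners


def _aggregate(job: _ScopeJob, ntd_cols: np.ndarray, R: np.ndarray,
               P: np.ndarray) -> np.ndarray:
    """Turn an (F, n_scope) nearest-distance block into observed values.

    Dataset/group: w_a * mean_j ntd(a, j) over the scope's samples, with
    w_a the mean relative abundance over occupied samples; features absent
    from every scope sample come back NaN.  Pairwise: an (F, n_partners)
    matrix f_{a,focal} * ntd(a, j).
    """
    if job.focal_idx is None:
        Psub = P[job.sample_idx]                      # n x F
        k = Psub.sum(axis=0)                          # occupied samples
        valid = ~np.isnan(ntd_cols)                   # F x n
        m = valid.sum(axis=1)
        with np.errstate(invalid="ignore"):
            w = (R[job.sample_idx] * Psub).sum(axis=0) / np.maximum(k, 1)
            mean_ntd = (np.where(valid, ntd_cols, 0.0).sum(axis=1)
                        / np.maximum(m, 1))
        vals = w * mean_ntd
        vals[k == 0] = np.nan      # absent from the whole scope
        vals[m == 0] = np.nan      # no defined comparison at all
        return vals
    f = R[job.focal_idx]                              # F
    vals = f[:, None] * ntd_cols                      # F x n_partners
    vals[f == 0, :] = np.nan
    return vals


def _permutations(n_feat: int, cfg: NullConfig, rng: np.random.Generator):
    if cfg.exhaustive:
        if n_feat > cfg.exhaustive_cap:
            raise ValidationError(
                f"exhaustive null over {n_feat} tips exceeds the cap of "
                f"{cfg.exhaustive_cap}; use the sampled null instead")
        return [np.array(p) for p in itertools.permutations(range(n_feat))]
    return [rng.permutation(n_feat) for _ in range(cfg.n_null)]


def _compute(table: CommunityTable, D: DistanceMatrix, jobs: list[_ScopeJob],
             cfg: NullConfig) -> list[dict]:
    """Observed values and null replicate values for every scope job.

    One shared tip permutation per replicate is applied across all jobs,
    features and partners; abundances are never shuffled.
    """
    D = D.reorder(table.features)
    R = to_relative(table).values()
    P = table.presence()
    Dv = D.values
    n_feat = Dv.shape[0]

    needed = sorted({int(i) for job in jobs for i in job.sample_idx})
    pos = {i: c for c, i in enumerate(needed)}
    col_of = {id(job): np.array([pos[int(i)] for i in job.sample_idx])
              for job in jobs}

    rng = np.random.default_rng(cfg.seed)
    perms = _permutations(n_feat, cfg, rng)
    n_rep = len(perms)
    if cfg.exhaustive:
        eps = np.zeros((n_rep, n_feat))
    else:
        eps = rng.uniform(cfg.noise_low, cfg.noise_high, size=(n_rep, n_feat))

    ntd_obs = _ntd_matrix(Dv, P[needed], cfg.allow_conspecifics)
    out = []
    for job in jobs:
        obs = _aggregate(job, ntd_obs[:, col_of[id(job)]], R, P)
        nulls = np.empty((n_rep,) + obs.shape)
        out.append({"job": job, "obs": obs, "nulls": nulls})

    for r, perm in enumerate(perms):
        Dp = Dv[np.ix_(perm, perm)]
        ntd_r = _ntd_matrix(Dp, P[needed], cfg.allow_conspecifics)
        for entry in out:
            job = entry["job"]
            vals = _aggregate(job, ntd_r[:, col_of[id(job)]], R, P)
            e = eps[r] if vals.ndim == 1 else eps[r][:, None]
            entry["nulls"][r] = vals + e

    for entry in out:
        nulls = entry["nulls"]
        entry["null_mean"] = nulls.mean(axis=0)
        entry["null_sd"] = (nulls.std(axis=0, ddof=1) if n_rep > 1
                            else np.full(entry["obs"].shape, np.nan))
    return out


def _zscore(obs, mean, sd):
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    z = np.where(np.isnan(obs), np.nan, z)
    return z


# ---------------------------------------------------------------------------
# public operations


def _scope_job(scope: Scope, table: CommunityTable) -> _ScopeJob:
    missing = [s for s in scope.samples if s not in table.samples]
    if missing:
        raise ValidationError(f"scope samples not in table: {missing[:5]}")
    row = {s: i for i, s in enumerate(table.samples)}
    if scope.mode == "pairwise":
        partners = [s for s in scope.samples if s != scope.focal]
        if not partners:
            raise ValidationError("pairwise scope needs at least one partner")
        return _ScopeJob(scope.label,
                         np.array([row[s] for s in partners]),
                         focal_idx=row[scope.focal])
    return _ScopeJob(scope.label, np.array([row[s] for s in scope.samples]))


def feature_bmntd(a: str, scope: Scope, table: CommunityTable,
                  D: DistanceMatrix, cfg: NullConfig | None = None):
    """Observed feature-level beta-MNTD for one feature.

    Dataset/group scope returns a float; pairwise scope returns a dict
    mapping partner sample to the per-partner value.  NaN marks a feature
    absent from every scope sample.
    """
    cfg = cfg or NullConfig()
    D = D.reorder(table.features)
    job = _scope_job(scope, table)
    R = to_relative(table).values()
    P = table.presence()
    ntd = _ntd_matrix(D.values, P[job.sample_idx], cfg.allow_conspecifics)
    vals = _aggregate(job, ntd, R, P)
    ai = table.features.index(a)
    if vals.ndim == 1:
        return float(vals[ai])
    partners = [s for s in scope.samples if s != scope.focal]
    return {p: float(vals[ai, c]) for c, p in enumerate(partners)}


def null_distribution(a: str, scope: Scope, table: CommunityTable,
                      D: DistanceMatrix, cfg: NullConfig | None = None):
    """Null replicate values of the feature-level beta-MNTD for one feature.

    Dataset/group: a 1-D array of length ``n_null`` (or of the number of
    distinct permutations when exhaustive).  Pairwise: dict partner -> array.
    """
    cfg = cfg or NullConfig()
    entry = _compute(table, D, [_scope_job(scope, table)], cfg)[0]
    ai = table.features.index(a)
    nulls = entry["nulls"]
    if nulls.ndim == 2:
        return nulls[:, ai].copy()
    partners = [s for s in scope.samples if s != scope.focal]
    return {p: nulls[:, ai, c].copy() for c, p in enumerate(partners)}


def feature_bnti(a: str, scope: Scope, table: CommunityTable,
                 D: DistanceMatrix, cfg: NullConfig | None = None):
    """Full record(s) for one feature (z-score against the shuffle null)."""
    cfg = cfg or NullConfig()
    recs = [r for r in run_scopes(table, D, [scope], cfg) if r.feature == a]
    if scope.mode != "pairwise":
        return recs[0]
    return {r.partner: r for r in recs}


def _records_for_entry(entry: dict, table: CommunityTable, scope: Scope,
                       cfg: NullConfig) -> list[FeatureAssemblyRecord]:
    job = entry["job"]
    obs, mean, sd = entry["obs"], entry["null_mean"], entry["null_sd"]
    z = _zscore(obs, mean, sd)
    R = to_relative(table).values()
    P = table.presence()
    feats = table.features
    recs: list[FeatureAssemblyRecord] = []
    if job.focal_idx is None:
        Psub = P[job.sample_idx]
        k = Psub.sum(axis=0)
        with np.errstate(invalid="ignore"):
            w = (R[job.sample_idx] * Psub).sum(axis=0) / np.maximum(k, 1)
        n_ubiq = int(np.sum((k == len(job.sample_idx)) & (obs == 0)))
        if n_ubiq and cfg.allow_conspecifics and not cfg.exhaustive:
            log.warning(
                "%d feature(s) in scope %r are conspecific in every sample; "
                "their z is pinned near -2.6 by the injected noise",
                n_ubiq, job.label)
        for i, a in enumerate(feats):
            if k[i] == 0:
                recs.append(FeatureAssemblyRecord(
                    a, job.label, None, np.nan, np.nan, np.nan, np.nan,
                    np.nan, ContributionCategory.ABSENT))
            else:
                recs.append(FeatureAssemblyRecord(
                    a, job.label, None, float(w[i]), float(obs[i]),
                    float(mean[i]), float(sd[i]), float(z[i]),
                    classify(float(z[i]))))
        return recs
    partners = [s for s in scope.samples if s != scope.focal]
    f = R[job.focal_idx]
    pres_focal = P[job.focal_idx]
    n_consp = int(np.sum((obs == 0) & pres_focal[:, None]
                         & P[job.sample_idx].T))
    if n_consp and cfg.allow_conspecifics and not cfg.exhaustive:
        log.warning(
            "%d (feature, partner) pair(s) with focal %r are conspecific; "
            "their z is pinned near -2.6 by the injected noise",
            n_consp, scope.focal)
    for i, a in enumerate(feats):
        for c, p in enumerate(partners):
            if f[i] == 0:
                recs.append(FeatureAssemblyRecord(
                    a, job.label, p, np.nan, np.nan, np.nan, np.nan,
                    np.nan, ContributionCategory.ABSENT))
            else:
                recs.append(FeatureAssemblyRecord(
                    a, job.label, p, float(f[i]), float(obs[i, c]),
                    float(mean[i, c]), float(sd[i, c]), float(z[i, c]),
                    classify(float(z[i, c]))))
    return recs


def run_scopes(table: CommunityTable, D: DistanceMatrix,
               scopes: Sequence[Scope],
               cfg: NullConfig | None = None) -> list[FeatureAssemblyRecord]:
    """Run the metric over explicit scopes sharing one permutation stream."""
    cfg = cfg or NullConfig()
    jobs = [_scope_job(s, table) for s in scopes]
    entries = _compute(table, D, jobs, cfg)
    recs: list[FeatureAssemblyRecord] = []
    for scope, entry in zip(scopes, entries):
        recs.extend(_records_for_entry(entry, table, scope, cfg))
    return recs


def run(table: CommunityTable, D: DistanceMatrix, mode: str = "dataset", *,
        groups: Mapping[str, str] | pd.Series | None = None,
        focal: str | None = None,
        samples: Sequence[str] | None = None,
        cfg: NullConfig | None = None) -> list[FeatureAssemblyRecord]:
    """Driver for the three calculation modes.

    ``dataset``: one record per feature over all samples (or ``samples``).
    ``group``: one record per feature per group; ``groups`` maps sample ->
    group label and nulls are drawn within each group's samples only.
    ``pairwise``: one record per feature per non-focal sample.
    """
    cfg = cfg or NullConfig()
    base = tuple(samples) if samples is not None else table.samples
    if mode == "dataset":
        scopes = [Scope("dataset", base, label="dataset")]
    elif mode == "group":
        if groups is None:
            raise ValidationError("group mode requires a sample -> group map")
        gmap = dict(groups.items()) if hasattr(groups, "items") else dict(groups)
        unknown = [s for s in gmap if s not in table.samples]
        if unknown:
            raise ValidationError(f"group map names unknown samples: {unknown[:5]}")
        order: dict[str, list[str]] = {}
        for s in base:
            if s in gmap:
                order.setdefault(str(gmap[s]), []).append(s)
        if not order:
            raise ValidationError("group map covers none of the scope samples")
        scopes = [Scope("group", tuple(ss), label=g) for g, ss in order.items()]
    elif mode == "pairwise":
        if focal is None:
            raise ValidationError("pairwise mode requires a focal sample")
        if focal not in table.samples:
            raise ValidationError(f"focal sample {focal!r} not in table")
        if focal not in base:
            base = (focal,) + base
        scopes = [Scope("pairwise", base, focal=focal)]
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return run_scopes(table, D, scopes, cfg)


def records_to_frame(records: Iterable[FeatureAssemblyRecord],
                     cfg: NullConfig | None = None) -> pd.DataFrame:
    """Tabulate records (the TSV layout written by the CLI)."""
    rows = [{
        "feature": r.feature,
        "scope_label": r.scope_label,
        "partner": r.partner if r.partner is not None else "",
        "abundance_weight": r.abundance_weight,
        "bmntd_obs": r.bmntd_obs,
        "null_mean": r.null_mean,
        "null_sd": r.null_sd,
        "bnti": r.bnti,
        "category": r.category.value,
    } for r in records]
    df = pd.DataFrame(rows)
    if cfg is not None and len(df):
        df["n_null"] = cfg.n_null
        df["seed"] = cfg.seed
    return df
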
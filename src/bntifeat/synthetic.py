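"""Synthetic fixtures with known assembly regimes.

Random Yule trees, neutral communities (presence independent of the tree —
the calibration case where feature-level z-scores should be standard
normal), selection-structured communities with known convergent or
divergent clades (the power case), and random but chemically plausible
molecular-formula tables.  Everything is seeded; there is no global random
state.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .formulas import FormulaRecord, derived_properties
from .relational_io import (
    CommunityTable,
    Dendrogram,
    ValidationError,
    cophenetic_matrix,
    parse_newick,
)

log = logging.getLogger("bntifeat")

__all__ = [
    "ScenarioSpec",
    "random_tree",
    "neutral_communities",
    "structured_communities",
    "random_formula_table",
]

# monoisotopic atomic masses (Da)
MASS = {"C": 12.0, "H": 1.00782503207, "O": 15.99491461956,
        "N": 14.0030740048, "S": 31.97207100, "P": 30.97376163}


@dataclass(frozen=True)
class ScenarioSpec:
    """A structured-community scenario.

    ``regime``: ``clade_filter`` plants a monophyletic clade whose tips
    co-occur at boosted occupancy in every sample (expected convergent);
    ``group_contrast`` restricts one clade to one half of the samples and a
    disjoint clade to the other half (expected divergent in dataset mode).
    ``selection_strength`` in [0, 1] interpolates from neutral (0) to full
    selection (1); ``target_clade`` is either a tip subset (must be
    monophyletic) or a fraction of tips, in which case a clade of about
    that size is chosen to embody the regime: the most phylogenetically
    compact clade for ``clade_filter`` (a conserved niche is a compact
    clade) and the most isolated clade (largest minimum distance to any
    outside tip, i.e. a distinct lineage) for ``group_contrast``.
    """

    n_tips: int = 100
    n_samples: int = 20
    regime: str = "neutral"
    target_clade: tuple[str, ...] | float = 0.12
    selection_strength: float = 0.5
    occupancy: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("neutral", "clade_filter", "group_contrast"):
            raise ValidationError(f"unknown regime {self.regime!r}")
        if not (0 <= self.selection_strength <= 1):
            raise ValidationError("selection_strength must be in [0, 1]")
        if not (0 < self.occupancy <= 1):
            raise ValidationError("occupancy must be in (0, 1]")


def random_tree(n_tips: int, seed: int) -> Dendrogram:
    """Yule-process topology (pure birth) with exponential branch lengths."""
    if n_tips < 2:
        raise ValidationError("need n_tips >= 2")
    t = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=random.Random(seed))
    for i, leaf in enumerate(t.leaf_node_iter()):
        leaf.taxon.label = f"F{i + 1:04d}"
    newick = t.as_string(schema="newick", suppress_rooting=True)
    return parse_newick(newick)


def _abundances(rng: np.random.Generator, presence: np.ndarray) -> pd.DataFrame:
    ab = rng.lognormal(mean=0.0, sigma=1.0, size=presence.shape)
    return np.where(presence, ab, 0.0)


def _resample_empty(rng, presence_fn, n_samples):
    """Draw each sample's presence row, redrawing empty rows (logged)."""
    rows = []
    for s in range(n_samples):
        row = presence_fn(s)
        tries = 0
        while not row.any():
            tries += 1
            if tries > 1000:
                raise ValidationError("occupancy too low: samples stay empty")
            row = presence_fn(s)
        if tries:
            log.info("resampled sample %d %d time(s) to avoid emptiness",
                     s, tries)
        rows.append(row)
    return np.array(rows)


def neutral_communities(tree: Dendrogram, n_samples: int, occupancy: float,
                        seed: int) -> CommunityTable:
    """Presence Bernoulli(occupancy) independent of the tree; log-normal
    abundances.  Assembly is tree-independent by construction."""
    if not (0 < occupancy <= 1):
        raise ValidationError("occupancy must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_feat = len(tree.tips)
    presence = _resample_empty(
        rng, lambda s: rng.random(n_feat) < occupancy, n_samples)
    data = pd.DataFrame(_abundances(rng, presence),
                        index=[f"S{j + 1:03d}" for j in range(n_samples)],
                        columns=list(tree.tips))
    return CommunityTable(data, "counts")


def _clades(tree: Dendrogram) -> list[tuple[str, ...]]:
    out = []
    for node in tree.tree.non_tips(include_self=False):
        tips = tuple(t.name for t in node.tips())
        if 2 <= len(tips) < len(tree.tips):
            out.append(tips)
    return out


def _pick_clade(tree: Dendrogram, fraction: float, objective: str,
                exclude: set[str] = frozenset()) -> tuple[str, ...]:
    """Pick a monophyletic clade of about ``fraction`` of the tips.

    ``objective="compact"`` minimises the mean within-clade cophenetic
    distance (a conserved-niche clade, the convergence scenario);
    ``objective="isolated"`` maximises the minimum distance from the clade
    to any outside tip (a distinct lineage, the divergence scenario).
    Candidate sizes lie within [0.5, 1.6] x the requested size.
    """
    n = len(tree.tips)
    lo = max(2, int(round(0.5 * fraction * n)))
    hi = max(lo, int(round(1.6 * fraction * n)))
    D = cophenetic_matrix(tree)
    idx = D.index()
    best, best_score = None, -np.inf
    for clade in _clades(tree):
        if not (lo <= len(clade) <= hi) or exclude & set(clade):
            continue
        sel = np.array([idx[t] for t in clade])
        if objective == "compact":
            sub = D.values[np.ix_(sel, sel)]
            score = -sub[np.triu_indices(len(sel), k=1)].mean()
        else:
            rest = np.array([idx[t] for t in tree.tips if t not in clade])
            score = D.values[np.ix_(sel, rest)].min()
        if score > best_score:
            best, best_score = clade, score
    if best is None:
        raise ValidationError(
            f"no monophyletic clade of ~{fraction:.0%} of {n} tips available")
    return best


def _check_monophyletic(tree: Dendrogram, tips: tuple[str, ...]) -> None:
    names = set(tips)
    if not names.issubset(set(tree.tips)):
        raise ValidationError("target clade names unknown tips")
    mrca = tree.tree.lca([t for t in tree.tree.tips() if t.name in names])
    span = {t.name for t in mrca.tips()}
    if span != names:
        raise ValidationError(
            f"target clade is not monophyletic (MRCA spans {len(span)} tips)")


def structured_communities(tree: Dendrogram, spec: ScenarioSpec
                           ) -> tuple[CommunityTable, pd.DataFrame]:
    """Communities with a planted selection signal plus per-feature truth.

    Returns the table and a truth frame (index feature, column ``label`` in
    {expected_convergent, expected_divergent, background}; group_contrast
    additionally returns a ``group`` column per sample via ``attrs``).
    At selection_strength 0 every regime reduces to the neutral generator.
    """
    if spec.regime == "neutral":
        table = neutral_communities(tree, spec.n_samples, spec.occupancy,
                                    spec.seed)
        truth = pd.DataFrame({"label": "background"}, index=list(tree.tips))
        return table, truth

    objective = "compact" if spec.regime == "clade_filter" else "isolated"
    if isinstance(spec.target_clade, tuple):
        target = spec.target_clade
        _check_monophyletic(tree, target)
    else:
        target = _pick_clade(tree, float(spec.target_clade), objective)
    tips = list(tree.tips)
    n_feat = len(tips)
    t_idx = np.isin(tips, target)
    rng = np.random.default_rng(spec.seed)
    occ, s = spec.occupancy, spec.selection_strength
    boosted = occ + s * (1 - occ)

    if spec.regime == "clade_filter":
        probs = np.where(t_idx, boosted, occ)
        presence = _resample_empty(
            rng, lambda _: rng.random(n_feat) < probs, spec.n_samples)
        truth = pd.DataFrame(
            {"label": np.where(t_idx, "expected_convergent", "background")},
            index=tips)
        groups = None
    else:  # group_contrast
        frac = (float(spec.target_clade)
                if not isinstance(spec.target_clade, tuple)
                else len(target) / n_feat)
        other = _pick_clade(tree, frac, "isolated", exclude=set(target))
        o_idx = np.isin(tips, other)
        half = spec.n_samples // 2
        in_a = np.arange(spec.n_samples) < (spec.n_samples - half)
        p_a = np.where(t_idx, boosted, np.where(o_idx, occ * (1 - s), occ))
        p_b = np.where(o_idx, boosted, np.where(t_idx, occ * (1 - s), occ))
        presence = _resample_empty(
            rng, lambda j: rng.random(n_feat) < (p_a if in_a[j] else p_b),
            spec.n_samples)
        truth = pd.DataFrame(
            {"label": np.where(t_idx | o_idx, "expected_divergent",
                               "background")}, index=tips)
        groups = ["A" if a else "B" for a in in_a]

    data = pd.DataFrame(_abundances(rng, presence),
                        index=[f"S{j + 1:03d}" for j in range(spec.n_samples)],
                        columns=tips)
    table = CommunityTable(data, "counts")
    if groups is not None:
        truth.attrs["sample_groups"] = dict(zip(data.index, groups))
    return table, truth


def random_formula_table(n: int, seed: int) -> list[FormulaRecord]:
    """Chemically plausible random molecular formulas.

    Element counts are drawn from ranges typical of FTICR-MS assignments
    (C 5-50, H 6-80, O 1-30, N/S/P 0-3 skewed toward 0) and redrawn when
    chemically impossible (DBE < 0 or H > 2C + 2 + N); masses are neutral
    monoisotopic.
    """
    if n < 2:
        raise ValidationError("need n >= 2 formulas")
    rng = np.random.default_rng(seed)
    hetero_p = np.array([0.55, 0.25, 0.15, 0.05])
    records: list[FormulaRecord] = []
    i = 0
    while len(records) < n:
        c = int(rng.integers(5, 51))
        h = int(rng.integers(6, 81))
        o = int(rng.integers(1, 31))
        nn = int(rng.choice(4, p=hetero_p))
        s = int(rng.choice(4, p=hetero_p))
        p = int(rng.choice(4, p=hetero_p))
        dbe = 1 + (2 * c - h + nn + p) / 2
        if dbe < 0 or h > 2 * c + 2 + nn:
            continue
        i += 1
        mass = (c * MASS["C"] + h * MASS["H"] + o * MASS["O"]
                + nn * MASS["N"] + s * MASS["S"] + p * MASS["P"])
        rec = FormulaRecord(f"MF{i:05d}", c=c, h=h, o=o, n=nn, s=s, p=p,
                            mass=mass)
        records.append(derived_properties(rec))
    return records
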
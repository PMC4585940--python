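"""Markov scores, signal-category collapse, and differential comparison.

A peptide's **Markov score** in one condition is the number of reactions
(out of R = biological x technical replicates, R = 6 by default) in which
its spot was called significantly phosphorylated above background — an
integer between 0 (never) and 6 (in all six reactions).

Scores are collapsed onto **signal categories**: for each upstream-kinase
category c, the fraction ``f_c`` of its member peptides with Markov score
>= tau (tau = 4 of 6 by default, i.e. phosphorylated in a majority of
reactions). Two conditions are contrasted per category by
``delta = f_B - f_A``; significance is assessed by a permutation test that
reshuffles category membership over all categorized peptides (preserving
category sizes), with Benjamini–Hochberg correction across categories.
The permutation layer is an addition of this package: the underlying
grey-scale category contrast is qualitative, and the test makes it
quantitative and calibrated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .array_model import ArrayLayout, StudyDesign
from .calling import NO_CALL, PHOSPHORYLATED, PhosphoCallSet

__all__ = [
    "KinomeProfile",
    "CategorySummary",
    "DifferentialCategoryTable",
    "markov_scores",
    "category_fractions",
    "differential_categories",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class KinomeProfile:
    """Per-peptide integer Markov scores for one condition.

    ``markov[p]`` counts reactions in which peptide p was called
    phosphorylated; ``n_called[p]`` counts reactions with a usable call
    (bad spots yield no call). Invariant: 0 <= markov <= n_called <= R.
    """

    condition: str
    R: int
    peptide_ids: tuple[str, ...]
    markov: np.ndarray
    n_called: np.ndarray

    def __eq__(self, other) -> bool:
        if not isinstance(other, KinomeProfile):
            return NotImplemented
        return (
            self.condition == other.condition
            and self.R == other.R
            and self.peptide_ids == other.peptide_ids
            and np.array_equal(self.markov, other.markov)
            and np.array_equal(self.n_called, other.n_called)
        )

    def __post_init__(self) -> None:
        n = len(self.peptide_ids)
        m = np.asarray(self.markov, dtype=int)
        nc = np.asarray(self.n_called, dtype=int)
        object.__setattr__(self, "markov", m)
        object.__setattr__(self, "n_called", nc)
        if m.shape != (n,) or nc.shape != (n,):
            raise ValueError("markov and n_called must align 1:1 with peptide_ids")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if np.any(m < 0) or np.any(m > nc) or np.any(nc > self.R):
            raise ValueError("profile violates 0 <= markov <= n_called <= R")


@dataclass(frozen=True)
class CategorySummary:
    """Phosphorylated fraction per signal category at threshold tau.

    ``f[c]`` = |{member peptides with Markov score >= tau}| / n[c]; this is
    the grey-scale value of a category-collapsed kinome profile.
    """

    condition: str
    tau: int
    categories: tuple[str, ...]
    n: np.ndarray
    f: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {c: float(v) for c, v in zip(self.categories, self.f)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": self.categories, "n": self.n, "fraction": self.f}
        )


@dataclass(frozen=True)
class DifferentialCategoryTable:
    """Per-category differential signaling between two conditions.

    Columns of ``table``: category, n, f_A, f_B, delta (= f_B - f_A),
    p_value (permutation, add-one estimator), q_value (Benjamini–Hochberg
    across categories).
    """

    condition_a: str
    condition_b: str
    tau: int
    n_perm: int
    table: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q_value"] < alpha]


def markov_scores(
    calls: list[PhosphoCallSet],
    layout: ArrayLayout,
    design: StudyDesign | None = None,
) -> KinomeProfile:
    """Count per-peptide phosphorylated calls across one condition's reactions.

    All call sets must share one condition and appear once per
    (bio_rep, tech_rep). R is taken from ``design`` when given, otherwise
    from the number of call sets supplied.
    """
    if not calls:
        raise ValueError("need at least one call set")
    conditions = {c.condition for c in calls}
    if len(conditions) != 1:
        raise ValueError(f"call sets span multiple conditions: {sorted(conditions)}")
    keys = [(c.bio_rep, c.tech_rep) for c in calls]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise ValueError(f"duplicate reaction (bio_rep, tech_rep) = {dup}")
    for c in calls:
        if c.peptide_ids != layout.peptide_ids:
            raise ValueError(f"call set {c.key} is not aligned with the layout")
    R = design.R if design is not None else len(calls)
    if len(calls) > R:
        raise ValueError(f"{len(calls)} call sets exceed design R = {R}")

    states = np.stack([c.states for c in calls])
    markov = (states == PHOSPHORYLATED).sum(axis=0)
    n_called = (states != NO_CALL).sum(axis=0)
    return KinomeProfile(
        condition=calls[0].condition,
        R=R,
        peptide_ids=layout.peptide_ids,
        markov=markov,
        n_called=n_called,
    )


def _eligible_mask(profile: KinomeProfile) -> np.ndarray:
    """Peptides scored in at least half of the design's reactions.

    A Markov score derived from fewer than R/2 usable reactions is not
    interpretable as a fraction of the design; such peptides are dropped
    from category collapse (with a log line) but kept in the profile.
    """
    mask = profile.n_called * 2 >= profile.R
    dropped = int((~mask).sum())
    if dropped:
        logger.info(
            "%s: dropping %d peptide(s) scored in fewer than half of %d reactions",
            profile.condition,
            dropped,
            profile.R,
        )
    return mask


def category_fractions(
    profile: KinomeProfile, layout: ArrayLayout, tau: int = 4
) -> CategorySummary:
    """Collapse a Markov-score profile onto signal categories.

    ``f_c`` is the fraction of category members with Markov score >= tau.
    Uncategorized peptides are excluded; categories left with zero
    eligible members are omitted.
    """
    if not 1 <= tau <= profile.R:
        raise ValueError(f"tau must be in 1..{profile.R}, got {tau}")
    if profile.peptide_ids != layout.peptide_ids:
        raise ValueError("profile is not aligned with the layout")
    eligible = _eligible_mask(profile)
    hits = profile.markov >= tau
    index = layout.index_of()
    cats, ns, fs = [], [], []
    for cat, members in layout.category_members().items():
        idx = np.array([index[m] for m in members])
        idx = idx[eligible[idx]]
        if idx.size == 0:
            continue
        cats.append(cat)
        ns.append(idx.size)
        fs.append(float(hits[idx].mean()))
    return CategorySummary(
        condition=profile.condition,
        tau=tau,
        categories=tuple(cats),
        n=np.array(ns, dtype=int),
        f=np.array(fs, dtype=float),
    )


def differential_categories(
    profile_a: KinomeProfile,
    profile_b: KinomeProfile,
    layout: ArrayLayout,
    tau: int = 4,
    n_perm: int = 10_000,
    seed: int = 0,
) -> DifferentialCategoryTable:
    """Permutation test of per-category phosphorylated-fraction differences.

    The observed statistic per category is |delta| with
    delta = f_B - f_A. The null reshuffles category membership labels over
    all categorized eligible peptides (category sizes preserved; one joint
    shuffle serves every category) and recomputes |delta| ``n_perm``
    times. p = (1 + #{null >= observed}) / (1 + n_perm) — the add-one
    estimator, so p is never zero — followed by Benjamini–Hochberg
    adjustment across categories. Deterministic given ``seed``.
    """
    if profile_a.peptide_ids != layout.peptide_ids or (
        profile_b.peptide_ids != layout.peptide_ids
    ):
        raise ValueError("profiles are not aligned with the layout")
    if profile_a.R != profile_b.R:
        raise ValueError("profiles have different R")
    if not 1 <= tau <= profile_a.R:
        raise ValueError(f"tau must be in 1..{profile_a.R}, got {tau}")
    if n_perm < 100:
        warnings.warn(
            f"n_perm = {n_perm} is very low; p-values will be coarse",
            stacklevel=2,
        )

    # Peptides enter only if eligible (scored in >= R/2 reactions) in both
    # conditions, so every category keeps one shared denominator.
    eligible = _eligible_mask(profile_a) & _eligible_mask(profile_b)
    hits_a = (profile_a.markov >= tau) & eligible
    hits_b = (profile_b.markov >= tau) & eligible

    index = layout.index_of()
    member_idx: dict[str, np.ndarray] = {}
    for cat, members in layout.category_members().items():
        idx = np.array([index[m] for m in members])
        idx = idx[eligible[idx]]
        if idx.size:
            member_idx[cat] = idx
    if not member_idx:
        raise ValueError("no category has any eligible member peptide")

    categorized = np.unique(np.concatenate(list(member_idx.values())))
    # d in {-1, 0, +1}: direction of the call change per peptide.
    d = hits_b.astype(np.int8) - hits_a.astype(np.int8)
    d_cat = d[categorized]
    pos_of = {p: i for i, p in enumerate(categorized)}

    cats = list(member_idx)
    obs_delta = np.array([float(d[member_idx[c]].mean()) for c in cats])

    rng = np.random.default_rng(seed)
    perm = rng.permuted(
        np.broadcast_to(d_cat, (n_perm, d_cat.size)).copy(), axis=1
    )
    exceed = np.zeros(len(cats), dtype=np.int64)
    for k, c in enumerate(cats):
        cols = np.array([pos_of[p] for p in member_idx[c]])
        null_delta = np.abs(perm[:, cols].mean(axis=1))
        exceed[k] = int((null_delta >= abs(obs_delta[k]) - 1e-12).sum())
    p = (1.0 + exceed) / (1.0 + n_perm)
    q = multipletests(p, method="fdr_bh")[1]

    f_a = np.array([float(hits_a[member_idx[c]].mean()) for c in cats])
    f_b = np.array([float(hits_b[member_idx[c]].mean()) for c in cats])
    table = pd.DataFrame(
        {
            "category": cats,
            "n": [member_idx[c].size for c in cats],
            "f_A": f_a,
            "f_B": f_b,
            "delta": f_b - f_a,
            "p_value": p,
            "q_value": q,
        }
    )
    return DifferentialCategoryTable(
        condition_a=profile_a.condition,
        condition_b=profile_b.condition,
        tau=tau,
        n_perm=n_perm,
        table=table,
    )
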
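"""Synthetic kinome-array studies with planted differential signaling.

Emulates a two-condition comparison (wild-type vs knockout lysates, e.g.
*Tsc2*-deficient MEFs) on a 1024-substrate peptide array, with three
technical replicates of two biological replicates per condition.

Generative model (all on the natural-log scale):

    log fg[p, c, b, t] = a_p + log m(p, c) + B[p, c, b] + T[p, c, b, t]

* ``a_p ~ Normal(baseline_log_mean, baseline_log_sd^2)`` is a per-peptide
  substrate affinity, drawn once and shared by both conditions — the same
  peptide is spotted on every array.
* ``m(p, c)`` is a multiplicative activity effect: ``activity_multipliers``
  for peptides of a planted category in condition ``c``,
  ``constitutive_multiplier`` for the constitutively active fraction of
  uncategorized peptides (active in both conditions), 1 otherwise.
* ``B`` is biological noise, a per-peptide perturbation shared by the
  technical replicates of one lysate; ``T`` is technical (per-reaction)
  noise. With ``sigma_tech <= sigma_bio`` technical replicates are more
  concordant than biological ones, as replicate QC expects.
* Background is drawn i.i.d. per spot from its own lognormal, independent
  of the signal.

Everything is reproducible from a single integer seed via documented
substreams, so identical configurations give byte-identical files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .array_model import (
    ArrayLayout,
    PeptideAnnotation,
    ReplicateQuantification,
    StudyDesign,
)

__all__ = [
    "GenerationConfig",
    "SyntheticTruth",
    "default_category_spec",
    "default_activity_multipliers",
    "make_layout",
    "simulate_study",
]

#: Substream indices for the per-stage random generators.
_STREAM_LAYOUT = 0
_STREAM_TRUTH = 1
_STREAM_SIGNAL = 2
_STREAM_BACKGROUND = 3

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Signal categories planted as activated on the knockout side by default.
PLANTED_CATEGORIES = ("mTOR", "p70S6K", "AMPK", "Chk1/Chk2", "PAK")

#: Additional categories carrying no differential effect by default.
NEUTRAL_CATEGORIES = (
    "PKA",
    "PKC",
    "CK2",
    "Src-family",
    "CDK",
    "MAPK/ERK",
    "GSK3",
    "CaMK2",
    "PI3K/Akt",
    "PLK",
)


def default_category_spec() -> dict[str, int]:
    """Default signal-category membership: 15 categories of 20 peptides."""
    spec = {c: 20 for c in PLANTED_CATEGORIES}
    spec.update({c: 20 for c in NEUTRAL_CATEGORIES})
    return spec


def default_activity_multipliers() -> dict[tuple[str, str], float]:
    """Knockout-side 4-fold activation of the five planted categories."""
    return {("KO", c): 4.0 for c in PLANTED_CATEGORIES}


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of one synthetic study.

    Defaults emulate the reference design: 1024 substrates, 2 biological x
    3 technical replicates per condition, knockout-side activation of the
    mTOR / p70S6K / AMPK / Chk1-Chk2 / PAK categories. Intensity units are
    arbitrary phosphor-imager counts; a baseline spot sits around
    exp(6.4) ~ 600 over a local background around exp(4.6) ~ 100.
    """

    n_peptides: int = 1024
    category_spec: Mapping[str, int] = field(default_factory=default_category_spec)
    design: StudyDesign = field(default_factory=StudyDesign)
    baseline_log_mean: float = math.log(600.0)
    baseline_log_sd: float = 0.4
    background_log_mean: float = math.log(100.0)
    background_log_sd: float = 0.3
    activity_multipliers: Mapping[tuple[str, str], float] = field(
        default_factory=default_activity_multipliers
    )
    constitutive_multiplier: float = 4.0
    frac_constitutive: float = 0.15
    sigma_bio: float = 0.15
    sigma_tech: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        total = sum(self.category_spec.values())
        if any(n < 1 for n in self.category_spec.values()):
            raise ValueError("category sizes must be >= 1")
        if total > self.n_peptides:
            raise ValueError(
                f"category_spec assigns {total} peptides but the array has "
                f"only {self.n_peptides}"
            )
        for (cond, cat), m in self.activity_multipliers.items():
            if m <= 0:
                raise ValueError(f"multiplier for {(cond, cat)} must be > 0")
            if cond not in self.design.conditions:
                raise ValueError(f"multiplier condition {cond!r} not in design")
            if cat not in self.category_spec:
                raise ValueError(f"multiplier category {cat!r} not in category_spec")
        if self.constitutive_multiplier <= 0:
            raise ValueError("constitutive_multiplier must be > 0")
        if not 0.0 <= self.frac_constitutive <= 1.0:
            raise ValueError("frac_constitutive must be in [0, 1]")
        for name in ("baseline_log_sd", "background_log_sd", "sigma_bio", "sigma_tech"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated study, for recovery tests.

    ``active_set[c]`` holds the peptides whose expected foreground exceeds
    the baseline in condition ``c`` (planted-category members plus the
    constitutively active peptides); ``planted_categories[c]`` the category
    labels with multiplier > 1 in ``c``.
    """

    active_set: dict[str, frozenset[str]]
    planted_categories: dict[str, frozenset[str]]

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "active_set": {c: sorted(v) for c, v in self.active_set.items()},
            "planted_categories": {
                c: sorted(v) for c, v in self.planted_categories.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            active_set={
                c: frozenset(v) for c, v in payload["active_set"].items()
            },
            planted_categories={
                c: frozenset(v) for c, v in payload["planted_categories"].items()
            },
        )


def _rng(config: GenerationConfig, stream: int) -> np.random.Generator:
    """Per-stage substream: SeedSequence(seed) spawned at a fixed key."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def make_layout(config: GenerationConfig) -> ArrayLayout:
    """Build a deterministic synthetic array layout.

    Peptides are laid out in blocks of 16 x 16 spots. Category members are
    chosen by a seeded shuffle of all positions; categories fill
    consecutive chunks of the shuffled order (hence disjoint), and the
    remaining peptides stay uncategorized. Substrate sequences are random
    13-mers — placeholders with no sequence semantics.
    """
    n = config.n_peptides
    rng = _rng(config, _STREAM_LAYOUT)
    width = max(4, len(str(n)))
    ids = [f"pep_{i + 1:0{width}d}" for i in range(n)]
    seqs = ["".join(rng.choice(_AMINO_ACIDS, size=13)) for _ in range(n)]

    cats: list[tuple[str, ...]] = [()] * n
    order = rng.permutation(n)
    pos = 0
    for cat, size in config.category_spec.items():
        for i in order[pos : pos + size]:
            cats[i] = (cat,)
        pos += size

    peptides = []
    for i in range(n):
        block, rem = divmod(i, 256)
        row, col = divmod(rem, 16)
        peptides.append(
            PeptideAnnotation(
                peptide_id=ids[i],
                grid=(block, row, col),
                categories=cats[i],
                substrate_seq=seqs[i],
            )
        )
    return ArrayLayout(peptides=tuple(peptides))


def _log_multiplier_matrix(
    config: GenerationConfig,
    layout: ArrayLayout,
    constitutive: frozenset[str],
) -> dict[str, np.ndarray]:
    """Per-condition vector of log activity multipliers, layout order."""
    out: dict[str, np.ndarray] = {}
    const_mask = np.array(
        [pid in constitutive for pid in layout.peptide_ids], dtype=bool
    )
    for cond in config.design.conditions:
        lm = np.zeros(layout.n_peptides)
        lm[const_mask] = math.log(config.constitutive_multiplier)
        for (c, cat), mult in config.activity_multipliers.items():
            if c != cond:
                continue
            member_mask = np.array(
                [cat in p.categories for p in layout.peptides], dtype=bool
            )
            lm[member_mask] += math.log(mult)
        out[cond] = lm
    return out


def simulate_study(
    config: GenerationConfig,
) -> tuple[ArrayLayout, list[ReplicateQuantification], SyntheticTruth]:
    """Simulate a complete two-condition study.

    Returns the layout, one quantification per reaction (conditions in
    design order, then bio_rep, then tech_rep), and the planted ground
    truth. Fully reproducible from ``config.seed``.
    """
    layout = make_layout(config)
    design = config.design

    rng_truth = _rng(config, _STREAM_TRUTH)
    uncategorized = [p.peptide_id for p in layout.peptides if not p.categories]
    n_const = int(round(config.frac_constitutive * len(uncategorized)))
    constitutive = frozenset(
        rng_truth.choice(uncategorized, size=n_const, replace=False)
    ) if n_const else frozenset()

    log_mult = _log_multiplier_matrix(config, layout, constitutive)

    planted = {
        cond: frozenset(
            cat
            for (c, cat), m in config.activity_multipliers.items()
            if c == cond and m > 1
        )
        for cond in design.conditions
    }
    active = {}
    for cond in design.conditions:
        ids = {
            pid
            for pid, lm in zip(layout.peptide_ids, log_mult[cond])
            if lm > 0
        }
        active[cond] = frozenset(ids)
    truth = SyntheticTruth(active_set=active, planted_categories=planted)

    n = layout.n_peptides
    rng_sig = _rng(config, _STREAM_SIGNAL)
    rng_bg = _rng(config, _STREAM_BACKGROUND)
    affinity = rng_sig.normal(config.baseline_log_mean, config.baseline_log_sd, n)

    quants: list[ReplicateQuantification] = []
    for cond in design.conditions:
        mu = affinity + log_mult[cond]
        for b in range(1, design.n_bio + 1):
            bio_noise = rng_sig.normal(0.0, config.sigma_bio, n)
            for t in range(1, design.n_tech + 1):
                tech_noise = rng_sig.normal(0.0, config.sigma_tech, n)
                fg = np.exp(mu + bio_noise + tech_noise)
                bg = np.exp(
                    rng_bg.normal(
                        config.background_log_mean, config.background_log_sd, n
                    )
                )
                quants.append(
                    ReplicateQuantification(
                        condition=cond,
                        bio_rep=b,
                        tech_rep=t,
                        peptide_ids=layout.peptide_ids,
                        foreground=fg,
                        background=bg,
                    )
                )
    return layout, quants, truth


def null_config(**overrides) -> GenerationConfig:
    """A no-differential-effect configuration (all multipliers 1).

    Useful for calibration checks: both conditions share the same
    generative law, so any detected category difference is a false
    positive.
    """
    base = GenerationConfig(activity_multipliers={})
    return replace(base, **overrides) if overrides else base
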
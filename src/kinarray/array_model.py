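"""Domain types and file dialects for peptide-array kinome data.

A kinome peptide array is a solid support spotted with short kinase
substrate peptides; incubation with a cell lysate and radiolabelled ATP
yields a per-spot phosphorylation signal read out on a phosphor imager.
This module defines the two tab-delimited dialects the pipeline speaks:

* the **layout** table mapping each peptide substrate to a grid position
  ``(block, row, col)`` and to zero or more upstream-kinase *signal
  categories* (e.g. ``mTOR``, ``PAK``, ``AMPK``, ``Chk1/Chk2``);
* per-reaction **quantification** tables holding each spot's foreground
  density and individual local background density, in arbitrary
  phosphor-imager units.

All readers validate against the layout, and all writers emit rows in
layout order so that outputs are byte-reproducible.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OK",
    "BAD_SPOT",
    "PeptideAnnotation",
    "ArrayLayout",
    "ReplicateQuantification",
    "StudyDesign",
    "read_layout",
    "write_layout",
    "default_layout",
    "read_quantification",
    "write_quantification",
    "parse_reaction_filename",
    "reaction_filename",
    "write_profile",
    "read_profile",
]

#: Spot status flags used in quantification files.
OK = "ok"
BAD_SPOT = "bad_spot"

_LAYOUT_REQUIRED = ("peptide_id", "block", "row", "col", "categories")
_QUANT_REQUIRED = ("peptide_id", "foreground_density", "background_density")
#: Accepted column aliases in quantification files (ScanAlyze exports vary).
_QUANT_ALIASES = {"spot_density": "foreground_density"}


class LayoutError(ValueError):
    """Raised when a layout table violates a structural invariant."""


class QuantificationError(ValueError):
    """Raised when a quantification table cannot be aligned to its layout."""


@dataclass(frozen=True)
class PeptideAnnotation:
    """One substrate peptide: identity, grid position, annotations.

    ``categories`` may be empty: such a peptide is still scored but is
    excluded from the signal-category collapse. Category labels are
    case-sensitive exact strings.
    """

    peptide_id: str
    grid: tuple[int, int, int]
    categories: tuple[str, ...] = ()
    substrate_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.peptide_id:
            raise LayoutError("peptide_id must be non-empty")
        if len(self.grid) != 3:
            raise LayoutError(
                f"grid must be a (block, row, col) triple, got {self.grid!r}"
            )


@dataclass(frozen=True)
class ArrayLayout:
    """The fixed map from peptide substrates to grid positions and categories.

    The layout's row order is the pipeline's stable total order: every
    downstream array (densities, calls, Markov scores) is aligned to
    ``peptide_ids`` and every writer emits rows in this order.
    """

    peptides: tuple[PeptideAnnotation, ...]

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        grids: dict[tuple[int, int, int], str] = {}
        for pep in self.peptides:
            if pep.peptide_id in seen:
                raise LayoutError(f"duplicate peptide_id {pep.peptide_id!r}")
            seen[pep.peptide_id] = 1
            if pep.grid in grids:
                raise LayoutError(
                    f"grid position {pep.grid} assigned to both "
                    f"{grids[pep.grid]!r} and {pep.peptide_id!r}"
                )
            grids[pep.grid] = pep.peptide_id

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def peptide_ids(self) -> tuple[str, ...]:
        return tuple(p.peptide_id for p in self.peptides)

    @property
    def categories(self) -> frozenset[str]:
        """Every category label attached to any peptide."""
        return frozenset(c for p in self.peptides for c in p.categories)

    def members(self, category: str) -> tuple[str, ...]:
        """Peptide ids annotated with ``category``, in layout order."""
        return tuple(
            p.peptide_id for p in self.peptides if category in p.categories
        )

    def category_members(self) -> dict[str, tuple[str, ...]]:
        """Map of every category to its member peptide ids (layout order)."""
        out: dict[str, tuple[str, ...]] = {}
        for p in self.peptides:
            for c in p.categories:
                out.setdefault(c, ())
        return {c: self.members(c) for c in out}

    def index_of(self) -> dict[str, int]:
        """Map peptide_id -> position in layout order."""
        return {p.peptide_id: i for i, p in enumerate(self.peptides)}


@dataclass(frozen=True)
class StudyDesign:
    """Replication scheme of a two-condition kinome comparison.

    The default mirrors a design of three technical replicates of two
    biological replicates per condition, i.e. R = 6 reactions per
    condition; a peptide's Markov score therefore ranges over 0..6.
    """

    conditions: tuple[str, str] = ("WT", "KO")
    n_bio: int = 2
    n_tech: int = 3

    def __post_init__(self) -> None:
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ValueError("design requires exactly two distinct conditions")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("n_bio and n_tech must be >= 1")

    @property
    def R(self) -> int:
        """Total reactions per condition."""
        return self.n_bio * self.n_tech

    def reactions(self) -> list[tuple[int, int]]:
        """All (bio_rep, tech_rep) pairs, 1-based, in deterministic order."""
        return [
            (b, t)
            for b in range(1, self.n_bio + 1)
            for t in range(1, self.n_tech + 1)
        ]


@dataclass(frozen=True)
class ReplicateQuantification:
    """Per-spot foreground/background densities for one reaction.

    Arrays are aligned 1:1 with the layout's peptide order. Densities are
    arbitrary phosphor-imager units, finite and non-negative. ``ok`` is a
    boolean mask; spots flagged ``bad_spot`` are carried through but are
    excluded from QC and never called (they become ``no_call``).
    """

    condition: str
    bio_rep: int
    tech_rep: int
    peptide_ids: tuple[str, ...]
    foreground: np.ndarray
    background: np.ndarray
    ok: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        fg = np.asarray(self.foreground, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        ok = (
            np.ones(len(self.peptide_ids), dtype=bool)
            if self.ok is None
            else np.asarray(self.ok, dtype=bool)
        )
        object.__setattr__(self, "foreground", fg)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "ok", ok)
        n = len(self.peptide_ids)
        if fg.shape != (n,) or bg.shape != (n,) or ok.shape != (n,):
            raise QuantificationError(
                "foreground, background and flags must align 1:1 with peptide_ids"
            )
        for name, arr in (("foreground", fg), ("background", bg)):
            if not np.all(np.isfinite(arr)):
                raise QuantificationError(f"{name} densities must be finite")
            if np.any(arr < 0):
                raise QuantificationError(f"{name} densities must be >= 0")
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise QuantificationError("bio_rep and tech_rep must be >= 1")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.condition, self.bio_rep, self.tech_rep)

    def check_aligned(self, layout: ArrayLayout) -> None:
        if self.peptide_ids != layout.peptide_ids:
            raise QuantificationError(
                f"reaction {self.key} is not aligned with the layout"
            )


# ---------------------------------------------------------------------------
# layout IO


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    for col in required:
        if col not in df.columns:
            raise LayoutError(f"{path}: missing required column {col!r}")


def read_layout(path: str | os.PathLike) -> ArrayLayout:
    """Read a tab-delimited array layout table.

    Expected header columns: ``peptide_id``, ``block``, ``row``, ``col``,
    optional ``substrate_seq``, and ``categories`` (semicolon-separated,
    possibly empty). File order is preserved and becomes the pipeline's
    canonical peptide order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _LAYOUT_REQUIRED, str(path))
    peptides = []
    for rec in df.itertuples(index=False):
        cats = tuple(c for c in str(rec.categories).split(";") if c)
        seq = getattr(rec, "substrate_seq", None)
        peptides.append(
            PeptideAnnotation(
                peptide_id=rec.peptide_id,
                grid=(int(rec.block), int(rec.row), int(rec.col)),
                categories=cats,
                substrate_seq=seq or None,
            )
        )
    return ArrayLayout(peptides=tuple(peptides))


def write_layout(path: str | os.PathLike, layout: ArrayLayout) -> None:
    """Write a layout table in the dialect read by :func:`read_layout`."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("peptide_id\tblock\trow\tcol\tsubstrate_seq\tcategories\n")
        for p in layout.peptides:
            b, r, c = p.grid
            fh.write(
                f"{p.peptide_id}\t{b}\t{r}\t{c}\t{p.substrate_seq or ''}\t"
                f"{';'.join(p.categories)}\n"
            )


def default_layout() -> ArrayLayout:
    """The package's default 1024-peptide array layout.

    A deterministic synthetic layout (4 blocks of 16 x 16 spots) with the
    default signal-category annotation scheme; shipped as data so that the
    examples and the command line work without any input files.
    """
    ref = resources.files("kinarray").joinpath("data/default_layout.tsv")
    with resources.as_file(ref) as p:
        return read_layout(p)


# ---------------------------------------------------------------------------
# reaction filename grammar


def parse_reaction_filename(name: str | os.PathLike) -> tuple[str, int, int]:
    """Parse ``<condition>_b<k>_t<m>.tsv`` into (condition, bio_rep, tech_rep).

    The condition label may itself contain underscores; the *last* two
    underscore-delimited tokens are taken as the replicate markers.
    """
    base = os.path.basename(os.fspath(name))
    stem, dot, ext = base.rpartition(".")
    if dot != "." or ext != "tsv":
        raise QuantificationError(f"{base!r}: expected a .tsv filename")
    parts = stem.split("_")
    if len(parts) < 3:
        raise QuantificationError(
            f"{base!r}: expected <condition>_b<k>_t<m>.tsv"
        )
    btok, ttok = parts[-2], parts[-1]
    condition = "_".join(parts[:-2])
    if not condition:
        raise QuantificationError(f"{base!r}: empty condition label")
    if btok[:1] != "b" or not btok[1:].isdigit():
        raise QuantificationError(f"{base!r}: bad biological-replicate token {btok!r}")
    if ttok[:1] != "t" or not ttok[1:].isdigit():
        raise QuantificationError(f"{base!r}: bad technical-replicate token {ttok!r}")
    bio, tech = int(btok[1:]), int(ttok[1:])
    if bio < 1 or tech < 1:
        raise QuantificationError(f"{base!r}: replicate numbers must be >= 1")
    return condition, bio, tech


def reaction_filename(condition: str, bio_rep: int, tech_rep: int) -> str:
    """Inverse of :func:`parse_reaction_filename`."""
    return f"{condition}_b{bio_rep}_t{tech_rep}.tsv"


# ---------------------------------------------------------------------------
# quantification IO


def read_quantification(
    path: str | os.PathLike,
    layout: ArrayLayout,
    *,
    condition: str | None = None,
    bio_rep: int | None = None,
    tech_rep: int | None = None,
) -> ReplicateQuantification:
    """Read one reaction's spot-quantification table, aligned to ``layout``.

    The file must contain exactly the layout's peptides (an error names the
    first offender otherwise). Reaction identity comes from the
    ``<condition>_b<k>_t<m>.tsv`` filename convention unless overridden by
    the explicit keyword arguments (explicit wins). A missing ``flag``
    column defaults every spot to ``ok``.
    """
    if condition is None or bio_rep is None or tech_rep is None:
        fc, fb, ft = parse_reaction_filename(path)
        condition = condition if condition is not None else fc
        bio_rep = bio_rep if bio_rep is not None else fb
        tech_rep = tech_rep if tech_rep is not None else ft

    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"peptide_id": str},
        keep_default_na=False,
        float_precision="round_trip",  # bit-exact read-back of written floats
    )
    df = df.rename(columns=_QUANT_ALIASES)
    _require_columns(df, _QUANT_REQUIRED, str(path))

    ids_in_file = list(df["peptide_id"])
    layout_ids = set(layout.peptide_ids)
    for pid in ids_in_file:
        if pid not in layout_ids:
            raise QuantificationError(
                f"{path}: peptide {pid!r} is not in the layout"
            )
    file_ids = set(ids_in_file)
    if len(file_ids) != len(ids_in_file):
        dup = next(p for p in ids_in_file if ids_in_file.count(p) > 1)
        raise QuantificationError(f"{path}: peptide {dup!r} appears more than once")
    for pid in layout.peptide_ids:
        if pid not in file_ids:
            raise QuantificationError(
                f"{path}: layout peptide {pid!r} is missing from the file"
            )

    df = df.set_index("peptide_id").loc[list(layout.peptide_ids)]
    fg = df["foreground_density"].astype(float).to_numpy()
    bg = df["background_density"].astype(float).to_numpy()
    if np.any(fg < 0) or np.any(bg < 0):
        bad = layout.peptide_ids[int(np.argmax((fg < 0) | (bg < 0)))]
        raise QuantificationError(f"{path}: negative density at peptide {bad!r}")
    if "flag" in df.columns:
        flags = df["flag"].astype(str).to_numpy()
        unknown = set(flags) - {OK, BAD_SPOT, ""}
        if unknown:
            raise QuantificationError(f"{path}: unknown flag value {unknown.pop()!r}")
        ok = (flags == OK) | (flags == "")
    else:
        ok = np.ones(layout.n_peptides, dtype=bool)
    return ReplicateQuantification(
        condition=condition,
        bio_rep=bio_rep,
        tech_rep=tech_rep,
        peptide_ids=layout.peptide_ids,
        foreground=fg,
        background=bg,
        ok=ok,
    )


def write_quantification(
    path: str | os.PathLike, quant: ReplicateQuantification
) -> None:
    """Write a quantification table losslessly (floats via shortest repr)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("peptide_id\tforeground_density\tbackground_density\tflag\n")
        for pid, f, b, good in zip(
            quant.peptide_ids, quant.foreground, quant.background, quant.ok
        ):
            flag = OK if good else BAD_SPOT
            fh.write(f"{pid}\t{float(f)!r}\t{float(b)!r}\t{flag}\n")


# ---------------------------------------------------------------------------
# profile IO (KinomeProfile lives in kinarray.scoring; imported lazily to
# keep the module dependency graph acyclic)


def write_profile(path: str | os.PathLike, profile) -> None:
    """Write a per-peptide Markov-score profile as TSV.

    Columns: peptide_id, markov_score, n_called, R, condition. Rows are in
    layout order; reading the file back with :func:`read_profile`
    reproduces the profile exactly.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("peptide_id\tmarkov_score\tn_called\tR\tcondition\n")
        for pid, m, nc in zip(
            profile.peptide_ids, profile.markov, profile.n_called
        ):
            fh.write(f"{pid}\t{int(m)}\t{int(nc)}\t{profile.R}\t{profile.condition}\n")


def read_profile(path: str | os.PathLike):
    """Read a profile written by :func:`write_profile`."""
    from .scoring import KinomeProfile

    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str})
    for col in ("peptide_id", "markov_score", "R"):
        if col not in df.columns:
            raise LayoutError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise LayoutError(f"{path}: profile file has no data rows")
    r_values = set(df["R"].astype(int))
    if len(r_values) != 1:
        raise LayoutError(f"{path}: inconsistent R values {sorted(r_values)}")
    cond = str(df["condition"].iloc[0]) if "condition" in df.columns else "unknown"
    n_called = (
        df["n_called"].astype(int).to_numpy()
        if "n_called" in df.columns
        else np.full(len(df), int(df["R"].iloc[0]))
    )
    return KinomeProfile(
        condition=cond,
        R=int(df["R"].iloc[0]),
        peptide_ids=tuple(df["peptide_id"]),
        markov=df["markov_score"].astype(int).to_numpy(),
        n_called=n_called,
    )
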
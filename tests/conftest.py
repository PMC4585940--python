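import numpy as np
import pytest

from kinarray.array_model import (
    ArrayLayout,
    PeptideAnnotation,
    ReplicateQuantification,
)
from kinarray.calling import BACKGROUND, NO_CALL, PHOSPHORYLATED, PhosphoCallSet


def make_layout(n, categories=None, seq=False):
    """Small ad-hoc layout: ids p1..pn, 4-wide rows, optional category map.

    ``categories`` maps peptide_id -> tuple of labels.
    """
    categories = categories or {}
    peptides = []
    for i in range(n):
        pid = f"p{i + 1}"
        peptides.append(
            PeptideAnnotation(
                peptide_id=pid,
                grid=(0, i // 4, i % 4),
                categories=tuple(categories.get(pid, ())),
                substrate_seq="AKRRRLSSLRA" if seq else None,
            )
        )
    return ArrayLayout(peptides=tuple(peptides))


def make_quant(layout, foreground, background=None, ok=None, condition="WT",
               bio_rep=1, tech_rep=1):
    n = layout.n_peptides
    fg = np.asarray(foreground, dtype=float)
    bg = np.zeros(n) if background is None else np.asarray(background, dtype=float)
    return ReplicateQuantification(
        condition=condition,
        bio_rep=bio_rep,
        tech_rep=tech_rep,
        peptide_ids=layout.peptide_ids,
        foreground=fg,
        background=bg,
        ok=None if ok is None else np.asarray(ok, dtype=bool),
    )


def calls_from_pattern(layout, phospho_mask, condition="WT", bio_rep=1,
                       tech_rep=1, no_call_mask=None):
    """Build a PhosphoCallSet from a boolean phosphorylated mask."""
    n = layout.n_peptides
    phospho = np.asarray(phospho_mask, dtype=bool)
    states = np.where(phospho, PHOSPHORYLATED, BACKGROUND).astype(np.int8)
    corrected = np.where(phospho, 1000.0, 1.0)
    if no_call_mask is not None:
        nc = np.asarray(no_call_mask, dtype=bool)
        states[nc] = NO_CALL
        corrected = np.where(nc, np.nan, corrected)
    posterior = np.where(states == NO_CALL, np.nan, phospho.astype(float))
    return PhosphoCallSet(
        condition=condition,
        bio_rep=bio_rep,
        tech_rep=tech_rep,
        peptide_ids=layout.peptide_ids,
        corrected=corrected,
        posterior=posterior,
        states=states,
    )


@pytest.fixture
def small_layout():
    return make_layout(8, {"p1": ("PAK", "mTOR"), "p2": ("PAK",), "p3": ("mTOR",)})
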
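"""Two-factor within-subject variance decomposition for repeated-measures designs.

Each subject's series is split at the diet switch into (subject x diet period)
cells. Subtracting the cell mean removes everything constant within a subject
and period — cage, sex, and the subject's own baseline — leaving the
within-subject component that carries the experimental perturbation signal.
The between component is the cell mean about the grand mean, so the centered
input reconstructs exactly as within + between and column variances add.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class Decomposition:
    """Additive split of a centered matrix into within- and between-cell parts."""

    within: np.ndarray
    between: np.ndarray
    cell_key: list[tuple]
    singleton_mask: np.ndarray  # samples in singleton cells, excluded from within

    def reconstruction(self) -> np.ndarray:
        return self.within + self.between


def within_subject_split(X: np.ndarray, subjects, diet=None,
                         treatment=None) -> Decomposition:
    """Decompose samples x variables matrix into within/between components.

    Cells are (subject, diet period); ``diet`` may be omitted for a plain
    subject-level split. ``treatment`` never varies within a subject, so it
    is absorbed by the between component and accepted only for interface
    symmetry. Singleton cells contribute zero within-rows and are flagged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(np.asarray(subjects)) != 1:
        X = X.T
    n = X.shape[0]
    subjects = np.asarray(subjects)
    if len(subjects) != n:
        raise ValueError("one subject label per sample required")
    if diet is None:
        cells = [(s,) for s in subjects]
    else:
        diet = np.asarray(diet)
        if len(diet) != n:
            raise ValueError("one diet label per sample required")
        cells = list(zip(subjects, diet))

    grand = X.mean(axis=0)
    centered = X - grand
    cell_means = pd.DataFrame(X).groupby(pd.Series(cells).apply(tuple)).transform("mean")
    cell_means = cell_means.to_numpy()
    within = X - cell_means
    between = cell_means - grand

    counts = pd.Series(cells).apply(tuple).map(
        pd.Series(cells).apply(tuple).value_counts())
    singleton = (counts.to_numpy() == 1)
    if singleton.any():
        log.warning("%d samples sit in singleton (subject, period) cells; "
                    "their within rows are zero", int(singleton.sum()))
    return Decomposition(within, between, [tuple(c) for c in cells], singleton)
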
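"""Ecoguild assignment from categorical diet and foraging-stratum data.

Species carry one diet label (8 vocabularies) and one foraging-stratum
label (9 vocabularies). The two blocks are one-hot encoded, column
centered, and decomposed by SVD; the quadrant of each species' scores on
the first two axes defines its ecoguild (1..4). Only co-membership matters
downstream — same-guild lineages interact in structured DD/MC models — so
the axis sign convention is fixed deterministically but the labels
themselves are arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DIET_LABELS",
    "FORAGE_LABELS",
    "CategoryTable",
    "GuildAssignment",
    "encode_onehot",
    "assign_ecoguilds",
]

DIET_LABELS = (
    "invertebrates",
    "terrestrial vertebrates",
    "fishes",
    "carrion",
    "fruit",
    "nectar",
    "seeds",
    "plants",
)
FORAGE_LABELS = (
    "ground",
    "understory",
    "mid-high",
    "canopy",
    "aerial",
    "pelagic-below-surface",
    "pelagic-above-surface",
    "nonpelagic-below-surface",
    "nonpelagic-above-surface",
)

_TIE_EPS = 1e-12


@dataclass
class CategoryTable:
    """Per-species diet and foraging-stratum labels."""

    species: list[str]
    diet: list[str]
    forage: list[str]

    def __post_init__(self):
        if not (len(self.species) == len(self.diet) == len(self.forage)):
            raise ValueError("species/diet/forage length mismatch")
        bad_diet = sorted(set(self.diet) - set(DIET_LABELS))
        bad_forage = sorted(set(self.forage) - set(FORAGE_LABELS))
        if bad_diet or bad_forage:
            raise ValueError(f"unknown labels: diet={bad_diet}, forage={bad_forage}")

    @classmethod
    def from_csv(cls, path) -> "CategoryTable":
        df = pd.read_csv(path)
        return cls(list(df["species"]), list(df["diet"]), list(df["forage"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": self.species, "diet": self.diet, "forage": self.forage}
        )


@dataclass
class GuildAssignment:
    """PCA scores and quadrant-coded guild (1..4) per species."""

    species: list[str]
    pc1: np.ndarray
    pc2: np.ndarray
    guild: np.ndarray  # int, 1=(+,+) 2=(-,+) 3=(-,-) 4=(+,-)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.species, self.guild.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": self.species, "pc1": self.pc1, "pc2": self.pc2, "guild": self.guild}
        )


def encode_onehot(table: CategoryTable) -> np.ndarray:
    """Species x 17 binary indicator matrix (8 diet + 9 forage columns)."""
    n = len(table.species)
    X = np.zeros((n, len(DIET_LABELS) + len(FORAGE_LABELS)))
    diet_index = {lab: j for j, lab in enumerate(DIET_LABELS)}
    forage_index = {lab: len(DIET_LABELS) + j for j, lab in enumerate(FORAGE_LABELS)}
    for i in range(n):
        X[i, diet_index[table.diet[i]]] = 1.0
        X[i, forage_index[table.forage[i]]] = 1.0
    return X


def _quadrant(pc1: float, pc2: float) -> int:
    # boundary ties go to the positive side
    xpos = pc1 >= -_TIE_EPS
    ypos = pc2 >= -_TIE_EPS
    if xpos and ypos:
        return 1
    if not xpos and ypos:
        return 2
    if not xpos and not ypos:
        return 3
    return 4


def assign_ecoguilds(table: CategoryTable) -> GuildAssignment:
    """Cluster species into <= 4 ecoguilds via PCA-quadrants of one-hot data.

    The indicator matrix is column centered and decomposed by SVD; scores on
    the first two axes are signed so that the largest-magnitude loading on
    each axis is positive (quadrant identity is otherwise arbitrary).
    """
    n = len(table.species)
    if n < 2:
        raise ValueError("need at least 2 species to assign ecoguilds")
    X = encode_onehot(table)
    Xc = X - X.mean(axis=0, keepdims=True)
    n_distinct = len({(d, f) for d, f in zip(table.diet, table.forage)})
    if n_distinct < 2:
        warnings.warn("all species share one category row: single degenerate guild")
        zeros = np.zeros(n)
        return GuildAssignment(list(table.species), zeros, zeros.copy(), np.ones(n, dtype=int))
    # SVD on a canonically row-sorted copy so the decomposition (and any
    # tie-breaking inside LAPACK) is invariant to species input order
    order = np.lexsort((np.array(table.forage), np.array(table.diet)))
    U, s, Vt = np.linalg.svd(Xc[order], full_matrices=False)
    scores = Xc @ Vt[:2].T  # n x 2
    for axis in range(2):
        j = int(np.argmax(np.abs(Vt[axis])))
        if Vt[axis, j] < 0:
            scores[:, axis] *= -1.0
    guild = np.array([_quadrant(a, b) for a, b in scores], dtype=int)
    return GuildAssignment(list(table.species), scores[:, 0], scores[:, 1], guild)
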
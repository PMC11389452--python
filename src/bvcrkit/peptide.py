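"""Composition-based survivin-binding prediction for peptides and proteins.

Protein sequences are tiled into 15-residue peptides with a 5-residue
step (10-residue overlap), each tile is encoded by the counts of
side-chain functional groups at every position (C-Pos: composition by
position), and a small feed-forward classifier (two hidden units) trained
on peptide-microarray fluorescence labels predicts binding. Two
per-protein summaries follow: R_bind, the fraction of a protein's tiles
predicted to bind, and M_bind(n), the fraction of the 19 possible
single-residue substitutions at position n (over every tile covering n)
whose mutant peptide is still predicted to bind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

TILE_LENGTH = 15
TILE_STEP = 5

# Intensity thresholds (fluorescence units): strict lower bounds.
STRONG_THRESHOLD = 30_000
MODERATE_THRESHOLD = 10_000
LOW_THRESHOLD = 1_000

#: Side-chain functional groups counted per residue. The backbone amide
#: shared by every residue is included so that composition, not only
#: side-chain identity, shapes the encoding. The table is this package's
#: own chemically-motivated assignment and is part of its configuration.
GROUPS = (
    "CH3", "CH2", "CH", "aromatic", "hydroxyl", "carboxyl", "amide",
    "sulfhydryl", "thioether", "guanidinium", "imidazole", "indole",
    "amine", "backbone_amide",
)

_SIDE_CHAINS: dict[str, dict[str, int]] = {
    "G": {},
    "A": {"CH3": 1},
    "V": {"CH": 1, "CH3": 2},
    "L": {"CH2": 1, "CH": 1, "CH3": 2},
    "I": {"CH": 1, "CH2": 1, "CH3": 2},
    "P": {"CH2": 3},
    "F": {"CH2": 1, "aromatic": 1},
    "Y": {"CH2": 1, "aromatic": 1, "hydroxyl": 1},
    "W": {"CH2": 1, "indole": 1},
    "S": {"CH2": 1, "hydroxyl": 1},
    "T": {"CH": 1, "CH3": 1, "hydroxyl": 1},
    "C": {"CH2": 1, "sulfhydryl": 1},
    "M": {"CH2": 2, "CH3": 1, "thioether": 1},
    "N": {"CH2": 1, "amide": 1},
    "Q": {"CH2": 2, "amide": 1},
    "D": {"CH2": 1, "carboxyl": 1},
    "E": {"CH2": 2, "carboxyl": 1},
    "K": {"CH2": 4, "amine": 1},
    "R": {"CH2": 3, "guanidinium": 1},
    "H": {"CH2": 1, "imidazole": 1},
}

AMINO_ACIDS = tuple(sorted(_SIDE_CHAINS))

_GROUP_INDEX = {g: i for i, g in enumerate(GROUPS)}
_RESIDUE_VECTORS = {}
for _aa, _groups in _SIDE_CHAINS.items():
    _v = np.zeros(len(GROUPS))
    for _g, _n in _groups.items():
        _v[_GROUP_INDEX[_g]] = _n
    _v[_GROUP_INDEX["backbone_amide"]] = 1
    _RESIDUE_VECTORS[_aa] = _v
_RESIDUE_VECTORS["X"] = np.zeros(len(GROUPS))  # unknown residue: null group vector


@dataclass(frozen=True)
class PeptideTile:
    """A 15-residue window of a protein; ``start`` is 1-based."""

    protein_id: str
    start: int
    sequence: str

    @property
    def end(self) -> int:
        """1-based inclusive index of the tile's last residue."""
        return self.start + len(self.sequence) - 1


def tile_protein(sequence: str, protein_id: str = "", k: int = TILE_LENGTH,
                 step: int = TILE_STEP, allow_x: bool = False) -> list[PeptideTile]:
    """Tile a protein into k-mers at the given step, covering the C-terminus.

    Tiles start at residues 1, 1+step, ...; when the last regular tile
    stops short of the C-terminus an extra tile anchored at L-k+1 is
    appended so every residue is covered.
    """
    sequence = sequence.upper()
    L = len(sequence)
    if L < k:
        raise ValueError(f"sequence length {L} shorter than tile length {k}")
    alphabet = set(_SIDE_CHAINS) | ({"X"} if allow_x else set())
    bad = set(sequence) - alphabet
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)}; pass allow_x=True "
                         "to map unknowns to a null group vector")
    starts = list(range(0, L - k + 1, step))
    if starts[-1] != L - k:
        starts.append(L - k)
    return [PeptideTile(protein_id, s + 1, sequence[s:s + k]) for s in starts]


def encode_cpos(sequence: str) -> np.ndarray:
    """C-Pos encoding: per-position functional-group counts, concatenated.

    A 15-residue peptide maps to a vector of length 15 * len(GROUPS),
    position-major, so swapping two unequal residues changes exactly the
    two corresponding blocks.
    """
    if len(sequence) != TILE_LENGTH:
        raise ValueError(f"expected a {TILE_LENGTH}-residue peptide")
    try:
        return np.concatenate([_RESIDUE_VECTORS[aa] for aa in sequence.upper()])
    except KeyError as exc:
        raise ValueError(f"residue {exc} missing from the group table") from exc


def encode_tiles(tiles: Iterable[PeptideTile | str]) -> np.ndarray:
    seqs = [t.sequence if isinstance(t, PeptideTile) else t for t in tiles]
    return np.vstack([encode_cpos(s) for s in seqs])


def label_intensity(intensity: float) -> str:
    """Ordinal binding label from fluorescence intensity."""
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    if intensity > STRONG_THRESHOLD:
        return "strong"
    if intensity > MODERATE_THRESHOLD:
        return "moderate"
    if intensity > LOW_THRESHOLD:
        return "low"
    return "none"


def label_tiles(tiles: Sequence[PeptideTile], intensities: Sequence[float],
                binding_threshold: float = MODERATE_THRESHOLD) -> pd.DataFrame:
    """Ordinal and binary labels per tile (binary: intensity strictly above
    the binding threshold, default the moderate boundary of 10,000)."""
    if len(tiles) != len(intensities):
        raise ValueError("one intensity per tile required")
    rows = []
    for t, v in zip(tiles, intensities):
        rows.append({
            "protein_id": t.protein_id, "start": t.start, "sequence": t.sequence,
            "intensity": float(v), "label": label_intensity(v),
            "binds": bool(v > binding_threshold),
        })
    return pd.DataFrame(rows)


class CompositionBindingClassifier(BaseEstimator, ClassifierMixin):
    """Two-hidden-unit MLP over C-Pos features with standard scaling.

    Training mirrors the microarray protocol: tiles ending in cysteine
    are excluded from training (they can form artifactual disulfide
    contacts on the array) but are still scored at prediction time; 90%
    of the remaining tiles train the model and the held-out 10% yields
    ``holdout_accuracy_``. Feature scaling statistics are fitted on the
    training split only and reused for any later input.

    The net is trained with L-BFGS under moderate L2 (``alpha``): with
    only two hidden units the unregularized loss surface invites
    memorization of the training tiles, while a weight penalty steers the
    fit toward the low-complexity composition rules the encoding is
    designed to expose.
    """

    def __init__(self, hidden_units: int = 2, train_fraction: float = 0.9,
                 binding_threshold: float = MODERATE_THRESHOLD,
                 alpha: float = 0.1, solver: str = "lbfgs",
                 max_iter: int = 5000, random_state: int = 0):
        self.hidden_units = hidden_units
        self.train_fraction = train_fraction
        self.binding_threshold = binding_threshold
        self.alpha = alpha
        self.solver = solver
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, tiles: Sequence[PeptideTile | str], y=None,
            intensities: Sequence[float] | None = None):
        """Fit from tiles plus either binary labels ``y`` or raw
        ``intensities`` (thresholded at ``binding_threshold``)."""
        seqs = [t.sequence if isinstance(t, PeptideTile) else t for t in tiles]
        if y is None:
            if intensities is None:
                raise ValueError("provide binary labels y or raw intensities")
            y = np.asarray(intensities, dtype=float) > self.binding_threshold
        y = np.asarray(y, dtype=bool)
        if len(seqs) != y.size:
            raise ValueError("one label per tile required")
        eligible = np.array([not s.endswith("C") for s in seqs])
        self.excluded_cterm_cys_ = int((~eligible).sum())
        idx = np.flatnonzero(eligible)
        if np.unique(y[idx]).size < 2:
            raise ValueError("training data must contain both classes")
        train_idx, test_idx = train_test_split(
            idx, train_size=self.train_fraction, random_state=self.random_state,
            stratify=y[idx])
        X = encode_tiles(seqs)
        self.pipeline_ = Pipeline([
            ("scaler", StandardScaler()),
            ("mlp", MLPClassifier(hidden_layer_sizes=(self.hidden_units,),
                                  alpha=self.alpha, solver=self.solver,
                                  max_iter=self.max_iter,
                                  random_state=self.random_state)),
        ])
        self.pipeline_.fit(X[train_idx], y[train_idx])
        self.train_index_ = train_idx
        self.test_index_ = test_idx
        self.holdout_accuracy_ = float(
            self.pipeline_.score(X[test_idx], y[test_idx]))
        self.classes_ = np.array([False, True])
        return self

    def predict(self, tiles: Sequence[PeptideTile | str]) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(encode_tiles(tiles))


def r_bind(sequence: str, model, k: int = TILE_LENGTH, step: int = TILE_STEP) -> float:
    """Fraction of a protein's tiles predicted to bind survivin."""
    tiles = tile_protein(sequence, k=k, step=step)
    pred = np.asarray(model.predict(tiles), dtype=bool)
    return float(pred.sum()) / len(tiles)


def _mutant_scan(sequence: str, position: int, k: int, step: int):
    """All single-residue mutants, at a 1-based position, of every tile
    covering that position. Yields mutated tile sequences."""
    L = len(sequence)
    if not (1 <= position <= L):
        raise ValueError(f"position {position} outside protein of length {L}")
    for tile in tile_protein(sequence, k=k, step=step):
        if not (tile.start <= position <= tile.end):
            continue
        off = position - tile.start
        for aa in AMINO_ACIDS:
            if aa == tile.sequence[off]:
                continue
            yield tile.sequence[:off] + aa + tile.sequence[off + 1:]


def m_bind(sequence: str, model, position: int,
           k: int = TILE_LENGTH, step: int = TILE_STEP) -> float:
    """Fraction of substitutions at ``position`` predicted to still bind.

    Every tile covering the position is mutated to each of the 19 other
    residues; the denominator is therefore 19 x (number of covering
    tiles). 1 means the region binds no matter the mutation; 0 means no
    mutation yields a predicted binder.
    """
    mutants = list(_mutant_scan(sequence, position, k, step))
    pred = np.asarray(model.predict(mutants), dtype=bool)
    return float(pred.sum()) / len(mutants)


def binding_profile(sequence: str, model, protein_id: str = "",
                    k: int = TILE_LENGTH, step: int = TILE_STEP) -> pd.DataFrame:
    """Per-residue M_bind plus the protein-level R_bind as a DataFrame."""
    rb = r_bind(sequence, model, k, step)
    rows = [{"protein_id": protein_id, "position": i + 1, "residue": aa,
             "m_bind": m_bind(sequence, model, i + 1, k, step), "r_bind": rb}
            for i, aa in enumerate(sequence)]
    return pd.DataFrame(rows)
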
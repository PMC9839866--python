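"""Cleavage-site context scoring and fusion-induced shift detection.

When a signal peptide is grafted onto a heterologous mature protein the
sequence context around the cleavage bond changes, and signal peptidase may
prefer a different bond than on the native precursor.  This module trains a
small position-specific log-odds matrix over the positions -3..-1 (last
three SP residues) and +1, +2 (first two mature residues) from a cohort of
annotated precursors, then re-scores every candidate bond within a window
around the annotated site of a fusion construct.  It is a transparent
stand-in for a full cleavage-site predictor: shift *fractions* are
meaningful on cohorts generated or annotated consistently with it, but the
matrix does not numerically reproduce neural-network predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io_formats import AMINO_ACIDS, SignalPeptide
from .feature_metrics import classify_triplet

#: positions scored around the cleavage bond (no position 0 exists)
MATRIX_POSITIONS = (-3, -2, -1, 1, 2)
DEFAULT_SEARCH_WINDOW = 5
MIN_TRAINING_COHORT = 20


@dataclass
class SiteWeightMatrix:
    """Log2-odds weights, positions -3..+2 x 20 residues."""

    weights: pd.DataFrame  # index: MATRIX_POSITIONS, columns: amino acids
    pseudocount: float
    n_trained: int

    def weight(self, position: int, aa: str) -> float:
        return float(self.weights.at[position, aa])

    def to_tsv(self, path) -> None:
        self.weights.to_csv(path, sep="\t", index_label="position",
                            float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, pseudocount: float = 1.0, n_trained: int = 0
                 ) -> "SiteWeightMatrix":
        df = pd.read_csv(path, sep="\t", index_col="position")
        return cls(weights=df, pseudocount=pseudocount, n_trained=n_trained)


@dataclass(frozen=True)
class CleavagePrediction:
    position: int  # 1-based last-SP-residue index in the fused sequence
    score: float
    shifted: bool
    new_triplet: str


def _context_residues(fused: str, position: int) -> Optional[dict[int, str]]:
    """Residues at MATRIX_POSITIONS for a candidate last-SP index (1-based);
    None when the context would run off either end."""
    out = {}
    for p in MATRIX_POSITIONS:
        # -1 is the last SP residue itself: 0-based index position - 1;
        # +1 is the first mature residue: 0-based index position.
        idx = position + p if p < 0 else position + p - 1
        if idx < 0 or idx >= len(fused):
            return None
        out[p] = fused[idx]
    return out


def train_site_matrix(
    cohort: Sequence[SignalPeptide],
    pseudocount: float = 1.0,
) -> SiteWeightMatrix:
    """Train the log-odds matrix from annotated precursors.

    Foreground counts come from each SP's cleavage context (its last three
    residues plus the first two residues of its native mature sequence);
    the background is the pooled residue frequency over all training
    sequences.  Both are smoothed with the same pseudocount so every weight
    is finite.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    usable = [sp for sp in cohort
              if sp.mature_prefix is not None and len(sp.mature_prefix) >= 2
              and len(sp.sp_seq) >= 3]
    if len(usable) < MIN_TRAINING_COHORT:
        raise ValueError(
            f"training cohort too small: {len(usable)} usable SPs "
            f"(need >= {MIN_TRAINING_COHORT} with mature context)"
        )
    fg = {p: {aa: 0 for aa in AMINO_ACIDS} for p in MATRIX_POSITIONS}
    bg_counts = {aa: 0 for aa in AMINO_ACIDS}
    for sp in usable:
        context = sp.sp_seq[-3:] + sp.mature_prefix[:2]
        for p, ch in zip(MATRIX_POSITIONS, context):
            if ch in fg[p]:
                fg[p][ch] += 1
        for ch in sp.sp_seq + sp.mature_prefix[:2]:
            if ch in bg_counts:
                bg_counts[ch] += 1

    n = len(usable)
    total_bg = sum(bg_counts.values())
    rows = {}
    for p in MATRIX_POSITIONS:
        row = {}
        for aa in AMINO_ACIDS:
            p_fg = (fg[p][aa] + pseudocount) / (n + 20 * pseudocount)
            p_bg = (bg_counts[aa] + pseudocount) / (total_bg + 20 * pseudocount)
            row[aa] = math.log2(p_fg) - math.log2(p_bg)
        rows[p] = row
    weights = pd.DataFrame(rows).T.loc[list(MATRIX_POSITIONS), list(AMINO_ACIDS)]
    return SiteWeightMatrix(weights=weights, pseudocount=pseudocount, n_trained=n)


def score_candidate(fused: str, position: int, matrix: SiteWeightMatrix) -> float:
    """Sum of matrix weights over the -3..+2 context at ``position``;
    -inf when the context is incomplete."""
    context = _context_residues(fused, position)
    if context is None:
        return float("-inf")
    total = 0.0
    for p, ch in context.items():
        if ch in matrix.weights.columns:
            total += matrix.weight(p, ch)
        # X or unknown residues contribute 0
    return total


def repredict_fusion(
    sp: SignalPeptide,
    mature_prefix: str,
    matrix: SiteWeightMatrix,
    search_window: int = DEFAULT_SEARCH_WINDOW,
) -> CleavagePrediction:
    """Best-scoring cleavage bond of the fusion ``sp_seq + mature_prefix``.

    Candidate last-SP-residue positions span the annotated site plus/minus
    ``search_window``, intersected with [4, len(fused) - 2]; the leftmost
    maximum wins, so exact ties keep the more amino-terminal site.
    """
    if len(mature_prefix) < 2:
        raise ValueError("mature_prefix must provide at least 2 residues")
    fused = sp.sp_seq + mature_prefix
    cp = sp.cleavage_pos
    lo = max(4, cp - search_window)
    hi = min(len(fused) - 2, cp + search_window)
    if lo > hi:
        raise ValueError(f"{sp.gene_id}: no admissible candidate positions")
    best_pos, best_score = lo, float("-inf")
    for j in range(lo, hi + 1):
        s = score_candidate(fused, j, matrix)
        if s > best_score:  # strict: leftmost wins ties
            best_pos, best_score = j, s
    return CleavagePrediction(
        position=best_pos,
        score=best_score,
        shifted=(best_pos != cp),
        new_triplet=fused[best_pos - 3 : best_pos],
    )


def shift_report(
    cohort: Sequence[SignalPeptide],
    matrix: SiteWeightMatrix,
    mature_prefix: Optional[str] = None,
    search_window: int = DEFAULT_SEARCH_WINDOW,
) -> pd.DataFrame:
    """Per-SP shift table for a fusion experiment.

    ``mature_prefix`` is the grafted protein's amino-terminal sequence; when
    None, each SP's own annotated ``mature_prefix`` is used.  Columns:
    original and newly predicted (-3,-1) triplets (also joined as
    "XYZ-XYZ"), the shifted flag, and whether the new site carries an
    AXA/VXA motif ("recovered" motif).
    """
    rows = []
    for sp in cohort:
        prefix = mature_prefix if mature_prefix is not None else sp.mature_prefix
        if prefix is None:
            raise ValueError(f"{sp.gene_id}: no mature prefix available")
        pred = repredict_fusion(sp, prefix, matrix, search_window=search_window)
        original = sp.sp_seq[-3:]
        new_class = classify_triplet(pred.new_triplet)
        rows.append(
            {
                "gene_id": sp.gene_id,
                "original_triplet": original,
                "new_triplet": pred.new_triplet,
                "motif_pair": f"{original}-{pred.new_triplet}",
                "predicted_position": pred.position,
                "shifted": pred.shifted,
                "new_motif_class": new_class,
                "recovered_motif": pred.shifted and new_class in ("AXA", "VXA"),
            }
        )
    return pd.DataFrame(rows)
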
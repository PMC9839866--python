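"""N/H/C region decomposition of signal peptides.

A signal peptide is conventionally split into a charged amino-terminal
N-region, a hydrophobic core H-region, and a short polar C-region that ends
at the signal-peptidase cleavage site.  When an annotation table already
carries region boundaries those are always used; otherwise this module
applies a deterministic hydropathy heuristic:

1. seed the H-core at the contiguous window of length ``min(7, len - 3)``
   with the maximum mean Kyte-Doolittle value (leftmost window on ties);
2. extend the core left and right while the adjacent residue has a
   Kyte-Doolittle value >= 1.0;
3. clip the core so that the N-region keeps >= 1 residue and the C-region
   keeps >= 2 residues (clipping from the H side nearer the violated bound).

The constants (seed window 7, extension threshold 1.0, leftmost tie-break)
are fixed, documented defaults so that every downstream statistic is
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import SignalPeptide

logger = logging.getLogger("sigpep")

#: Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SEED_WINDOW = 7
EXTENSION_THRESHOLD = 1.0
MIN_SP_LENGTH = 6


@dataclass(frozen=True)
class RegionDecomposition:
    """Residue counts of the N/H/C partition (n + h + c == SP length)."""

    n_len: int
    h_len: int
    c_len: int
    flagged: bool = False  # no hydrophobic core found; partition is nominal

    @property
    def total(self) -> int:
        return self.n_len + self.h_len + self.c_len


def _kd_values(seq: str) -> list[float | None]:
    vals: list[float | None] = []
    for ch in seq:
        if ch == "X":
            vals.append(None)
        else:
            try:
                vals.append(KYTE_DOOLITTLE[ch])
            except KeyError:
                raise ValueError(f"unknown residue {ch!r}") from None
    return vals


def _window_mean(vals: list[float | None], start: int, length: int) -> float:
    usable = [v for v in vals[start : start + length] if v is not None]
    if not usable:
        return float("-inf")
    return sum(usable) / len(usable)


def decompose_regions(sp_seq: str) -> RegionDecomposition:
    """Partition ``sp_seq`` into N/H/C by the hydropathy heuristic.

    Raises ``ValueError`` for sequences shorter than 6 residues.  A
    sequence with no hydrophobic core (all window means negative) is still
    partitioned — around the best available window — but the result is
    flagged and a warning logged.
    """
    L = len(sp_seq)
    if L < MIN_SP_LENGTH:
        raise ValueError(f"signal peptide too short to decompose (len={L} < {MIN_SP_LENGTH})")
    vals = _kd_values(sp_seq)

    w = min(SEED_WINDOW, L - 3)
    best_start, best_mean = 0, float("-inf")
    for start in range(0, L - w + 1):
        m = _window_mean(vals, start, w)
        if m > best_mean:  # strict: leftmost wins ties
            best_start, best_mean = start, m

    flagged = best_mean < 0
    if flagged:
        logger.warning(
            "no hydrophobic core (max window mean %.2f < 0); nominal partition", best_mean
        )

    h_start, h_end = best_start, best_start + w - 1  # inclusive, 0-based
    if not flagged:
        while h_start > 0:
            v = vals[h_start - 1]
            if v is not None and v >= EXTENSION_THRESHOLD:
                h_start -= 1
            else:
                break
        while h_end < L - 1:
            v = vals[h_end + 1]
            if v is not None and v >= EXTENSION_THRESHOLD:
                h_end += 1
            else:
                break

    # clip so the flanking regions keep their minimum lengths
    if h_start < 1:
        h_start = 1
    if h_end > L - 3:
        h_end = L - 3
    if h_start > h_end:  # degenerate after clipping; keep a 1-residue core
        h_start = h_end

    return RegionDecomposition(
        n_len=h_start,
        h_len=h_end - h_start + 1,
        c_len=L - 1 - h_end,
        flagged=flagged,
    )


def decomposition_for(sp: SignalPeptide) -> RegionDecomposition:
    """Annotation boundaries when present, else the heuristic."""
    if sp.has_boundaries:
        return RegionDecomposition(
            n_len=sp.n_end,
            h_len=sp.h_end - sp.n_end,
            c_len=sp.cleavage_pos - sp.h_end,
        )
    return decompose_regions(sp.sp_seq)


def validate_decomposition(sp: SignalPeptide, d: RegionDecomposition) -> list[str]:
    """Return the list of invariant violations (empty when valid)."""
    violations = []
    if d.total != len(sp.sp_seq):
        violations.append("length mismatch")
    if d.n_len < 1:
        violations.append("N-region empty")
    if d.h_len < 1:
        violations.append("H-region empty")
    if d.c_len < 2:
        violations.append("C-region too short")
    return violations


def region_slices(sp: SignalPeptide, d: RegionDecomposition) -> tuple[str, str, str]:
    """The (N, H, C) substrings of the SP under decomposition ``d``."""
    s = sp.sp_seq
    return s[: d.n_len], s[d.n_len : d.n_len + d.h_len], s[d.n_len + d.h_len :]
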
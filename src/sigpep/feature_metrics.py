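"""Per-SP and per-cohort sequence features.

Implements the feature set used to relate signal-peptide sequence to
secretion capacity: sliding-window Kyte-Doolittle hydropathy, the compound
hydrophobicity score (maximum window mean x H-region length), N-region net
charge, pooled per-region residue composition, per-position conservation
information content, the (-3,-1) cleavage-motif classes (AXA / VXA / other),
single-residue H-region deletion scans, and the hydrophobicity-threshold
classification of the translocation route (post-translational vs
SRP-dependent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io_formats import AMINO_ACIDS, SignalPeptide
from .region_model import (
    KYTE_DOOLITTLE,
    RegionDecomposition,
    decompose_regions,
    region_slices,
)

DEFAULT_WINDOW = 9
#: compound-score band associated with reduced secretion
DEFAULT_BAD_BAND = (23.0, 24.0)
#: max-window-mean thresholds separating translocation routes
DEFAULT_LOW_HYDRO = 1.75
DEFAULT_HIGH_HYDRO = 1.81

POSITIVE_RESIDUES = frozenset("KRH")  # His counted positive
NEGATIVE_RESIDUES = frozenset("DE")

MAX_INFORMATION_BITS = math.log2(20)


@dataclass(frozen=True)
class HydropathyProfile:
    window: int
    means: tuple[float, ...]

    @property
    def max_mean(self) -> float:
        return max(self.means)


@dataclass(frozen=True)
class CompoundScore:
    max_window_mean: float
    h_len: int
    score: float


@dataclass(frozen=True)
class MotifClass:
    klass: str  # AXA | VXA | OTHER
    triplet: str


def kd_window_profile(seq: str, window: int = DEFAULT_WINDOW) -> HydropathyProfile:
    """Mean Kyte-Doolittle value of every length-``window`` window.

    If the sequence is shorter than the window, a single mean over the whole
    sequence is returned (window shrunk to the sequence length).  ``X``
    residues are excluded from each window's mean.
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    eff = min(window, len(seq))
    vals = []
    for ch in seq:
        if ch == "X":
            vals.append(None)
        elif ch in KYTE_DOOLITTLE:
            vals.append(KYTE_DOOLITTLE[ch])
        else:
            raise ValueError(f"unknown residue {ch!r}")
    means = []
    for start in range(0, len(seq) - eff + 1):
        usable = [v for v in vals[start : start + eff] if v is not None]
        if not usable:
            raise ValueError("window contains only 'X' residues")
        means.append(sum(usable) / len(usable))
    return HydropathyProfile(window=eff, means=tuple(means))


def compound_score(
    sp: SignalPeptide,
    d: RegionDecomposition,
    window: int = DEFAULT_WINDOW,
) -> CompoundScore:
    """Maximum hydrophobic window mean over the whole SP times H-length."""
    profile = kd_window_profile(sp.sp_seq, window=window)
    m = profile.max_mean
    return CompoundScore(max_window_mean=m, h_len=d.h_len, score=m * d.h_len)


def n_region_charge(sp: SignalPeptide, d: RegionDecomposition) -> int:
    """Net charge of the N-region: (#K + #R + #H) - (#D + #E)."""
    n_region = sp.sp_seq[: d.n_len]
    pos = sum(ch in POSITIVE_RESIDUES for ch in n_region)
    neg = sum(ch in NEGATIVE_RESIDUES for ch in n_region)
    return pos - neg


def positive_residue_count(seq: str) -> int:
    return sum(ch in POSITIVE_RESIDUES for ch in seq)


def region_composition(
    cohort: Sequence[SignalPeptide],
    decompositions: Sequence[RegionDecomposition],
) -> pd.DataFrame:
    """Pooled residue fractions per region across the cohort.

    Returns a DataFrame indexed by region (N, H, C) with one column per
    canonical amino acid; each row sums to 1.  ``X`` residues are excluded.
    """
    if not cohort:
        raise ValueError("empty cohort")
    counts = {r: {aa: 0 for aa in AMINO_ACIDS} for r in "NHC"}
    for sp, d in zip(cohort, decompositions):
        for region, seq in zip("NHC", region_slices(sp, d)):
            for ch in seq:
                if ch in counts[region]:
                    counts[region][ch] += 1
    table = pd.DataFrame(counts).T.loc[list("NHC"), list(AMINO_ACIDS)].astype(float)
    totals = table.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("a region has no countable residues in this cohort")
    return table.div(totals, axis=0)


def positional_information(sequences: Sequence[str]) -> list[float]:
    """Per-position conservation in bits: log2(20) + sum p*log2(p).

    All sequences must have equal length and n >= 2; no small-sample
    correction is applied.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths {sorted(lengths)}")
    (L,) = lengths
    out = []
    for i in range(L):
        column = [s[i] for s in sequences if s[i] != "X"]
        n = len(column)
        if n == 0:
            out.append(0.0)
            continue
        entropy = 0.0
        for aa in set(column):
            p = column.count(aa) / n
            entropy -= p * math.log2(p)
        out.append(MAX_INFORMATION_BITS - entropy)
    return out


def classify_c_motif(sp: SignalPeptide) -> MotifClass:
    """Class of the (-3,-2,-1) triplet before the cleavage bond."""
    if len(sp.sp_seq) < 3:
        raise ValueError(f"{sp.gene_id}: SP shorter than 3 residues")
    triplet = sp.sp_seq[sp.cleavage_pos - 3 : sp.cleavage_pos]
    return MotifClass(klass=classify_triplet(triplet), triplet=triplet)


def classify_triplet(triplet: str) -> str:
    if len(triplet) != 3:
        raise ValueError(f"not a (-3,-1) triplet: {triplet!r}")
    if triplet[2] == "A":
        if triplet[0] == "A":
            return "AXA"
        if triplet[0] == "V":
            return "VXA"
    return "OTHER"


@dataclass(frozen=True)
class DeletionVariant:
    deleted_position: int  # 1-based position in the original SP
    variant_seq: str
    score: CompoundScore
    exits_bad_band: bool


def enumerate_single_deletions(
    sp: SignalPeptide,
    d: RegionDecomposition,
    bad_band: tuple[float, float] = DEFAULT_BAD_BAND,
    window: int = DEFAULT_WINDOW,
) -> list[DeletionVariant]:
    """All single-residue deletions within the H-region, re-decomposed and
    re-scored; a variant is flagged when the original score lies inside the
    bad band and the variant score leaves it."""
    if len(sp.sp_seq) < 7:
        raise ValueError(f"{sp.gene_id}: SP too short for deletion scan")
    lo, hi = bad_band
    original = compound_score(sp, d, window=window).score
    in_band = lo <= original <= hi
    variants = []
    for pos in range(d.n_len, d.n_len + d.h_len):  # 0-based H positions
        variant_seq = sp.sp_seq[:pos] + sp.sp_seq[pos + 1 :]
        vd = decompose_regions(variant_seq)
        v_sp = SignalPeptide(gene_id=f"{sp.gene_id}_del{pos + 1}", sp_seq=variant_seq)
        vs = compound_score(v_sp, vd, window=window)
        exits = in_band and not (lo <= vs.score <= hi)
        variants.append(
            DeletionVariant(
                deleted_position=pos + 1,
                variant_seq=variant_seq,
                score=vs,
                exits_bad_band=exits,
            )
        )
    return variants


def classify_translocation_bias(
    score_per_residue: float,
    low: float = DEFAULT_LOW_HYDRO,
    high: float = DEFAULT_HIGH_HYDRO,
) -> str:
    """Route classification from the per-residue max window mean.

    Weakly hydrophobic cores (<= ``low``) depend on the post-translational
    (Sec62/63, Sec72-assisted) pathway; strongly hydrophobic cores
    (>= ``high``) are SRP-biased; scores in between are intermediate.
    """
    if score_per_residue <= low:
        return "post_dependent"
    if score_per_residue >= high:
        return "srp_biased"
    return "intermediate"


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def feature_table(
    cohort: Sequence[SignalPeptide],
    decompositions: Sequence[RegionDecomposition],
    shifted: Optional[Sequence[bool]] = None,
    window: int = DEFAULT_WINDOW,
    low: float = DEFAULT_LOW_HYDRO,
    high: float = DEFAULT_HIGH_HYDRO,
) -> pd.DataFrame:
    """Per-SP feature table: regions, charge, scores, motif, route."""
    rows = []
    for i, (sp, d) in enumerate(zip(cohort, decompositions)):
        cs = compound_score(sp, d, window=window)
        motif = classify_c_motif(sp)
        rows.append(
            {
                "gene_id": sp.gene_id,
                "n_len": d.n_len,
                "h_len": d.h_len,
                "c_len": d.c_len,
                "n_charge": n_region_charge(sp, d),
                "max_window_mean": cs.max_window_mean,
                "compound_score": cs.score,
                "score_bin": round_half_away(cs.score),
                "motif_class": motif.klass,
                "triplet": motif.triplet,
                "translocation_bias": classify_translocation_bias(
                    cs.max_window_mean, low=low, high=high
                ),
                "location_label": sp.location_label,
                "titer": sp.titer,
                "shifted": bool(shifted[i]) if shifted is not None else None,
            }
        )
    return pd.DataFrame(rows)
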
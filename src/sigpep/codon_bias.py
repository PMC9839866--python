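"""Synonymous codon usage of SP coding regions versus the whole ORFeome.

The comparison is done on *within-family* codon fractions: for each amino
acid, the proportion of each synonymous codon among all codons encoding that
amino acid in a sequence set.  Stop codons are excluded.  "Rare" codons are
operationalized as family members whose reference (ORFeome) fraction falls
strictly below a configurable quantile of their family's fractions
(single-codon families contribute no rare codons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger("sigpep")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, standard nuclear code, stop codons excluded
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)
#: amino acid -> sorted tuple of synonymous codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

DEFAULT_RARE_QUANTILE = 0.25


@dataclass
class CodonFractionTable:
    """Within-family codon fractions plus per-amino-acid codon totals."""

    fractions: dict[str, dict[str, float]]  # aa -> codon -> fraction
    counts: dict[str, int]  # aa -> total codons observed

    def fraction(self, codon: str) -> float:
        return self.fractions[CODON_TO_AA[codon]][codon]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"amino_acid": aa, "codon": codon, "fraction": frac,
             "family_count": self.counts[aa]}
            for aa, fam in self.fractions.items()
            for codon, frac in fam.items()
        ]
        return pd.DataFrame(rows)


def _iter_codons(bases: str) -> Iterable[str]:
    for i in range(0, len(bases), 3):
        yield bases[i : i + 3]


def codon_fractions(cds_set: Sequence[str]) -> CodonFractionTable:
    """Pooled within-family codon fractions over a set of in-frame CDS.

    Stop codons and codons containing ambiguous bases are excluded with a
    warning; an empty input set is a hard error.
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    counts: dict[str, dict[str, int]] = {
        aa: {c: 0 for c in fam} for aa, fam in SYNONYMOUS_FAMILIES.items()
    }
    n_stops = n_ambiguous = 0
    for bases in cds_set:
        if len(bases) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        for codon in _iter_codons(bases.upper()):
            aa = CODON_TO_AA.get(codon)
            if aa is None:
                if codon in STOP_CODONS:
                    n_stops += 1
                else:
                    n_ambiguous += 1
                continue
            counts[aa][codon] += 1
    if n_stops:
        logger.warning("excluded %d stop codon(s)", n_stops)
    if n_ambiguous:
        logger.warning("excluded %d codon(s) with ambiguous bases", n_ambiguous)

    fractions: dict[str, dict[str, float]] = {}
    totals: dict[str, int] = {}
    for aa, fam in counts.items():
        total = sum(fam.values())
        totals[aa] = total
        if total == 0:
            fractions[aa] = {c: float("nan") for c in fam}
        else:
            fractions[aa] = {c: k / total for c, k in fam.items()}
    return CodonFractionTable(fractions=fractions, counts=totals)


def compare_fractions(
    sp_table: CodonFractionTable, all_table: CodonFractionTable
) -> pd.DataFrame:
    """Per-codon delta (SP fraction minus ORFeome fraction).

    Within every amino-acid family the deltas sum to zero (both inputs are
    normalized within family).
    """
    rows = []
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        for codon in fam:
            sp_f = sp_table.fractions[aa][codon]
            all_f = all_table.fractions[aa][codon]
            rows.append(
                {
                    "amino_acid": aa,
                    "codon": codon,
                    "sp_fraction": sp_f,
                    "all_fraction": all_f,
                    "delta": sp_f - all_f,
                }
            )
    return pd.DataFrame(rows)


def rare_codons(
    reference: CodonFractionTable, rare_quantile: float = DEFAULT_RARE_QUANTILE
) -> frozenset[str]:
    """Codons whose reference fraction is strictly below the within-family
    ``rare_quantile`` quantile; families of size 1 contribute none."""
    rare: set[str] = set()
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        if len(fam) < 2:
            continue
        fracs = np.array([reference.fractions[aa][c] for c in fam])
        if np.isnan(fracs).any():
            continue
        cutoff = float(np.quantile(fracs, rare_quantile))
        for codon, f in zip(fam, fracs):
            if f < cutoff:
                rare.add(codon)
    return frozenset(rare)


def rare_codon_share(
    sp_cds: str,
    reference: CodonFractionTable,
    rare_quantile: float = DEFAULT_RARE_QUANTILE,
) -> float:
    """Fraction of an SP's codons that are rare relative to the reference."""
    rare = rare_codons(reference, rare_quantile=rare_quantile)
    total = n_rare = 0
    for codon in _iter_codons(sp_cds.upper()):
        if CODON_TO_AA.get(codon) is None:
            continue
        total += 1
        if codon in rare:
            n_rare += 1
    if total == 0:
        raise ValueError("SP CDS contains no countable codons")
    return n_rare / total
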
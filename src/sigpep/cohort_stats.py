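"""Cohort-level descriptive summaries and the composite secretion-rule report.

Brings the per-SP features together: exact-sequence deduplication,
chromosome distribution of SP-containing genes, region-length histograms,
mean secretion titer per feature category, and a per-SP report of how many
of the empirically favourable "secretion rules" each SP satisfies
(N-region of 5 residues, H-region of 8-9, C-region of 5, net N-charge +1,
AXA/VXA motif, compound score outside the unfavourable 23-24 band, and an
unshifted cleavage site in the fusion context).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import SignalPeptide
from .region_model import RegionDecomposition

RULE_COLUMNS = [
    "rule_n_len_5",
    "rule_h_len_8_9",
    "rule_c_len_5",
    "rule_charge_plus1",
    "rule_motif",
    "rule_score_outside_band",
    "rule_not_shifted",
]

CATEGORIZERS = ("n_charge", "score_bin", "motif_class", "location_label", "shifted")


def dedupe(cohort: Sequence[SignalPeptide]) -> tuple[list[SignalPeptide], int]:
    """Drop SPs whose exact sequence was already seen (first kept, order
    preserved); returns (unique cohort, number removed)."""
    seen: set[str] = set()
    unique: list[SignalPeptide] = []
    for sp in cohort:
        if sp.sp_seq in seen:
            continue
        seen.add(sp.sp_seq)
        unique.append(sp)
    return unique, len(cohort) - len(unique)


def chromosome_distribution(
    cohort: Sequence[SignalPeptide],
    genes_per_chromosome: Mapping[str, int],
) -> pd.DataFrame:
    """Percentage of genes per chromosome that carry an SP."""
    for label, total in genes_per_chromosome.items():
        if total <= 0:
            raise ValueError(f"chromosome {label!r} has no genes")
    counts: dict[str, int] = {label: 0 for label in genes_per_chromosome}
    for sp in cohort:
        if sp.chromosome is None:
            continue
        if sp.chromosome not in counts:
            raise ValueError(f"{sp.gene_id}: unknown chromosome {sp.chromosome!r}")
        counts[sp.chromosome] += 1
    rows = [
        {
            "chromosome": label,
            "sp_genes": counts[label],
            "total_genes": genes_per_chromosome[label],
            "pct": 100.0 * counts[label] / genes_per_chromosome[label],
        }
        for label in genes_per_chromosome
    ]
    return pd.DataFrame(rows)


def length_distributions(
    cohort: Sequence[SignalPeptide],
    decompositions: Sequence[RegionDecomposition],
) -> dict:
    """Integer-binned counts and fractions of total/N/H/C lengths, plus the
    headline fraction of 5-residue C-regions."""
    totals = [len(sp.sp_seq) for sp in cohort]
    n = [d.n_len for d in decompositions]
    h = [d.h_len for d in decompositions]
    c = [d.c_len for d in decompositions]

    def hist(values: list[int]) -> pd.DataFrame:
        s = pd.Series(values).value_counts().sort_index()
        return pd.DataFrame(
            {"length": s.index, "count": s.values, "fraction": s.values / len(values)}
        )

    return {
        "total": hist(totals),
        "n": hist(n),
        "h": hist(h),
        "c": hist(c),
        "frac_c5": sum(v == 5 for v in c) / len(c) if c else float("nan"),
    }


def category_means(features: pd.DataFrame, by: str) -> pd.DataFrame:
    """Count, mean and SD of titers per category of a feature column.

    SPs without a titer are excluded from the means and reported in the
    ``n_untitered`` column; the SD is the sample SD (ddof=1, NaN for
    singleton categories).
    """
    if by not in features.columns:
        raise ValueError(f"unknown categorizer {by!r}")
    df = features.copy()
    df["_cat"] = df[by]
    rows = []
    for cat, group in df.groupby("_cat", dropna=False, sort=True):
        titers = group["titer"].dropna().astype(float)
        rows.append(
            {
                "category": cat,
                "count": int(len(group)),
                "n_titered": int(len(titers)),
                "n_untitered": int(len(group) - len(titers)),
                "mean_titer": float(titers.mean()) if len(titers) else float("nan"),
                "sd_titer": float(titers.std(ddof=1)) if len(titers) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def rule_report(
    features: pd.DataFrame,
    bad_band: tuple[float, float] = (23.0, 24.0),
) -> pd.DataFrame:
    """Per-SP boolean secretion-rule flags and the rule count, ranked by
    rule_count (desc) then compound_score (desc); deterministic for fixed
    input."""
    lo, hi = bad_band
    df = features.copy()
    df["rule_n_len_5"] = df["n_len"] == 5
    df["rule_h_len_8_9"] = df["h_len"].isin([8, 9])
    df["rule_c_len_5"] = df["c_len"] == 5
    df["rule_charge_plus1"] = df["n_charge"] == 1
    df["rule_motif"] = df["motif_class"].isin(["AXA", "VXA"])
    df["rule_score_outside_band"] = ~df["compound_score"].between(lo, hi)
    if "shifted" in df.columns and df["shifted"].notna().any():
        df["rule_not_shifted"] = ~df["shifted"].fillna(False).astype(bool)
    else:
        df["rule_not_shifted"] = False
    df["rule_count"] = df[RULE_COLUMNS].sum(axis=1).astype(int)
    df = df.sort_values(
        ["rule_count", "compound_score", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df
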
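"""Synthetic signal-peptide cohorts with known ground truth.

Generates full cohorts (SP protein sequences, SP coding sequences, a
background ORFeome, annotations, secretion titers) whose statistical
structure matches what the analysis stages assume: categorical N/H/C region
lengths, region-specific residue composition (positive-rich N, Leu-rich H,
Ala-rich C), planted (-3,-1) cleavage motifs at configured frequencies,
region-biased synonymous codon usage, a configurable fraction of SPs with a
degraded native cleavage context plus a planted strong downstream site in
the mature prefix (fusion-shift ground truth), and a feature-conditioned
log-normal titer model.  Every configured frequency and effect size is
recoverable by the corresponding analysis stage, which is the module's
reason to exist.

Determinism: one pseudo-random stream (``numpy.random.default_rng(seed)``);
no global state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import SignalPeptide, write_fasta, write_sp_table
from .feature_metrics import compound_score, n_region_charge
from .region_model import RegionDecomposition
from .codon_bias import SYNONYMOUS_FAMILIES

# ---------------------------------------------------------------------------
# default distributions (study conditions)
# ---------------------------------------------------------------------------

#: N-region length, 2..20 with mode 5 and a long right tail
N_LEN_DIST = {
    2: 0.06, 3: 0.10, 4: 0.16, 5: 0.28, 6: 0.14, 7: 0.09, 8: 0.06, 9: 0.04,
    10: 0.03, 11: 0.01, 12: 0.008, 13: 0.006, 14: 0.004, 15: 0.003,
    16: 0.002, 17: 0.002, 18: 0.002, 19: 0.002, 20: 0.001,
}
#: H-region length, 6..14 with mode 9
H_LEN_DIST = {6: 0.03, 7: 0.08, 8: 0.17, 9: 0.27, 10: 0.18, 11: 0.12,
              12: 0.08, 13: 0.04, 14: 0.03}
#: C-region length, 3..8; 5-residue C-regions dominate (64.38%)
C_LEN_DIST = {3: 0.04, 4: 0.12, 5: 0.6438, 6: 0.11, 7: 0.05, 8: 0.0362}


def _anchored(anchors: Mapping[str, float], base: Mapping[str, float]) -> dict[str, float]:
    """Fix the anchor residue probabilities exactly and scale the remaining
    base weights to fill the rest of the probability mass."""
    rest = 1.0 - sum(anchors.values())
    total = sum(w for aa, w in base.items() if aa not in anchors)
    dist = dict(anchors)
    for aa, w in base.items():
        if aa not in anchors:
            dist[aa] = w * rest / total
    return dist


#: N-region residue distribution for positions after the initial Met.
#: Anchors are calibrated so the *pooled* N-region composition (which
#: includes the invariant Met at position 1) realizes 22.37% positive
#: residues with Arg+Lys making up 87.86% of positives: the per-position
#: probabilities are the pooled targets scaled by E[n]/(E[n]-1).
N_RESIDUES = _anchored(
    {"K": 0.1436, "R": 0.0955, "H": 0.0331},
    {"S": 13, "T": 9, "A": 7, "N": 6, "Q": 5, "L": 7, "I": 4, "V": 5,
     "F": 3.5, "G": 6, "P": 4.5, "D": 2, "E": 2, "M": 4, "W": 0.8,
     "Y": 2.5, "C": 0.8},
)
#: H-region: Leu-rich hydrophobic core (26.59% Leu)
H_RESIDUES = _anchored(
    {"L": 0.2659},
    {"I": 13, "V": 14, "F": 12, "A": 16, "M": 5, "C": 3, "S": 9, "T": 6,
     "G": 6, "W": 3, "Y": 3, "P": 2, "K": 0.5, "R": 0.5, "D": 0.5,
     "E": 0.5, "N": 0.5, "Q": 0.5, "H": 0.5},
)
#: C-region residue distribution for positions other than (-3,-1).  The
#: Ala anchor is calibrated so the pooled C-region composition — including
#: the Ala planted at (-3,-1) by the AXA/VXA motif frequencies — realizes
#: 23.26% Ala: (E[c]-2) * x + p_axa + (p_axa + p_vxa) = 0.2326 * E[c].
C_RESIDUES = _anchored(
    {"A": 0.1865},
    {"S": 20, "T": 10, "G": 9, "V": 8, "L": 7, "P": 6, "Q": 5, "N": 5,
     "I": 4, "F": 3, "C": 2, "E": 1, "D": 1, "M": 2, "H": 1, "K": 0.5,
     "R": 0.5, "W": 1, "Y": 2},
)
#: mature-protein amino-terminal background: charged/hydrophobic-rich and
#: depleted in the small residues that signal peptidase selects at (-3,-1),
#: so the mature side of a fusion rarely mimics a cleavage context by chance
MATURE_RESIDUES = _anchored(
    {},
    {"D": 9, "E": 11, "K": 10, "R": 7, "L": 10, "I": 7, "V": 7, "F": 5,
     "N": 5, "Q": 5, "P": 5, "H": 3, "Y": 4, "M": 3, "W": 1.5, "A": 3,
     "S": 3.5, "T": 3, "G": 3, "C": 0.5},
)

#: intact native sites follow the small-residue (-3,-1) rule: when the
#: planted class is OTHER the two positions still carry small residues,
#: just not the Ala (or -3 Val) that would make an AXA/VXA motif
SMALL_MINUS3 = {"S": 0.38, "T": 0.26, "G": 0.22, "C": 0.14}
SMALL_MINUS1 = {"S": 0.45, "G": 0.30, "T": 0.15, "C": 0.10}
#: degraded native sites (shift-planted SPs) violate the small-residue rule
DEGRADED_SITE = _anchored(
    {},
    {"L": 12, "I": 8, "V": 8, "F": 6, "K": 10, "R": 8, "D": 9, "E": 10,
     "N": 7, "Q": 7, "Y": 5, "W": 2, "P": 5, "M": 3},
)
#: the two mature residues immediately after an intact cleavage site: a
#: charged amino-terminal block, the +1/+2 half of the recognizable context
MATURE_START = {"D": 0.34, "E": 0.33, "K": 0.22, "R": 0.11}

#: genes per chromosome of the synthetic genome (16 chromosomes, 6713 genes)
GENES_PER_CHROMOSOME = {
    "I": 120, "II": 420, "III": 180, "IV": 860, "V": 320, "VI": 140,
    "VII": 620, "VIII": 320, "IX": 240, "X": 430, "XI": 350, "XII": 600,
    "XIII": 540, "XIV": 440, "XV": 633, "XVI": 500,
}

LOCATION_PROBS = {
    "secreted": 0.30, "cell wall": 0.15, "cell membrane": 0.10,
    "membrane": 0.20, "ER": 0.10, "other": 0.15,
}

TRUTH_COLUMNS = [
    "true_n_len", "true_h_len", "true_c_len", "true_motif_class",
    "true_shifted", "true_n_charge", "true_compound_score",
    "true_flag_motif", "true_flag_charge_plus1", "true_flag_bad_band",
    "true_titer_multiplier",
]


@dataclass
class SynthParams:
    """Full generative specification of a synthetic SP cohort."""

    n_sps: int = 352
    n_duplicates: int = 30  # genes sharing an identical SP sequence
    seed: int = 0

    n_len_dist: dict = field(default_factory=lambda: dict(N_LEN_DIST))
    h_len_dist: dict = field(default_factory=lambda: dict(H_LEN_DIST))
    c_len_dist: dict = field(default_factory=lambda: dict(C_LEN_DIST))
    n_residues: dict = field(default_factory=lambda: dict(N_RESIDUES))
    h_residues: dict = field(default_factory=lambda: dict(H_RESIDUES))
    c_residues: dict = field(default_factory=lambda: dict(C_RESIDUES))
    mature_residues: dict = field(default_factory=lambda: dict(MATURE_RESIDUES))

    p_axa: float = 0.199
    p_vxa: float = 0.211
    p_shifted: float = 0.11
    shift_plant_offset: int = 3  # planted site: last-SP index cleavage_pos + offset
    mature_len: int = 12

    # codon model
    codon_skew: float = 0.5       # geometric within-family skew of the base model
    rare_boost: float = 2.0       # multiplier on rare-codon probability in SP CDS
    rare_quantile: float = 0.25
    n_orfs: int = 400
    orf_codons: tuple = (150, 450)

    # titer model (U/L)
    base_titer: float = 4106.0
    titer_sigma: float = 0.3
    mult_motif: float = 1.3
    mult_charge_plus1: float = 1.2
    mult_shifted: float = 0.51
    mult_bad_band: float = 0.7
    bad_band: tuple = (23.0, 24.0)

    genes_per_chromosome: dict = field(
        default_factory=lambda: dict(GENES_PER_CHROMOSOME))
    location_probs: dict = field(default_factory=lambda: dict(LOCATION_PROBS))

    def __post_init__(self) -> None:
        for name in ("n_len_dist", "h_len_dist", "c_len_dist", "n_residues",
                     "h_residues", "c_residues", "mature_residues",
                     "location_probs"):
            dist = getattr(self, name)
            total = sum(dist.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative probabilities")
        for name in ("p_axa", "p_vxa", "p_shifted"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        if self.p_axa + self.p_vxa > 1:
            raise ValueError("p_axa + p_vxa > 1")
        if self.p_shifted < 1 and self.p_axa + self.p_vxa > 1 - self.p_shifted:
            raise ValueError(
                "motif frequencies exceed the unshifted fraction; shifted SPs "
                "carry degraded (OTHER) native sites by construction"
            )
        if self.base_titer <= 0:
            raise ValueError("base_titer must be > 0")
        if not 0 <= self.n_duplicates < self.n_sps:
            raise ValueError("n_duplicates must be in [0, n_sps)")
        if self.mature_len < max(10, self.shift_plant_offset + 2):
            raise ValueError("mature_len too short")

    @classmethod
    def from_file(cls, path) -> "SynthParams":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) \
            else json.loads(text)
        for key in ("n_len_dist", "h_len_dist", "c_len_dist"):
            if key in data:
                data[key] = {int(k): float(v) for k, v in data[key].items()}
        for key in ("orf_codons", "bad_band"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def structured_params(**overrides) -> SynthParams:
    """Parameters for a strongly structured cohort: H-core mean hydropathy
    >= 2.5 and non-positive flank hydropathy, used for boundary-recovery
    validation of the decomposition heuristic."""
    flank = {aa: p for aa, p in
             {"K": 0.12, "R": 0.08, "S": 0.20, "T": 0.15, "N": 0.10,
              "Q": 0.10, "D": 0.05, "E": 0.05, "G": 0.10, "P": 0.05}.items()}
    core = {"L": 0.40, "I": 0.25, "V": 0.20, "F": 0.15}
    c_flank = {"S": 0.30, "T": 0.20, "N": 0.12, "Q": 0.12, "G": 0.16,
               "D": 0.02, "E": 0.02, "P": 0.06}
    defaults = dict(
        n_residues=flank, h_residues=core, c_residues=c_flank,
        p_axa=0.199, p_vxa=0.211,
    )
    defaults.update(overrides)
    return SynthParams(**defaults)


# ---------------------------------------------------------------------------
# codon model
# ---------------------------------------------------------------------------

def base_codon_model(skew: float = 0.5) -> dict[str, dict[str, float]]:
    """Per-amino-acid codon distribution with geometric within-family skew:
    the alphabetically first codon is most frequent, each next codon gets
    ``skew`` times the previous weight."""
    model = {}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        weights = np.array([skew ** i for i in range(len(fam))])
        weights /= weights.sum()
        model[aa] = dict(zip(fam, weights.tolist()))
    return model


def boosted_codon_model(
    base: Mapping[str, Mapping[str, float]],
    rare_boost: float,
    rare_quantile: float,
) -> dict[str, dict[str, float]]:
    """SP-region codon model: rare codons (below the within-family quantile
    of the base model) get their probability multiplied by ``rare_boost``
    and the family renormalized."""
    boosted = {}
    for aa, fam in base.items():
        codons = list(fam)
        probs = np.array([fam[c] for c in codons], dtype=float)
        if len(codons) > 1:
            cutoff = np.quantile(probs, rare_quantile)
            probs = np.where(probs < cutoff, probs * rare_boost, probs)
            probs /= probs.sum()
        boosted[aa] = dict(zip(codons, probs.tolist()))
    return boosted


def _back_translate(seq: str, model: Mapping[str, Mapping[str, float]],
                    rng: np.random.Generator) -> str:
    # draws are grouped per amino acid so long sequences stay cheap
    out: list[str] = [""] * len(seq)
    positions: dict[str, list[int]] = {}
    for i, aa in enumerate(seq):
        positions.setdefault(aa, []).append(i)
    for aa, idxs in positions.items():
        fam = model[aa]
        codons = list(fam)
        draws = rng.choice(len(codons), size=len(idxs), p=list(fam.values()))
        for i, k in zip(idxs, draws):
            out[i] = codons[k]
    return "".join(out)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _draw(dist: Mapping, rng: np.random.Generator):
    keys = list(dist)
    return keys[rng.choice(len(keys), p=list(dist.values()))]


def _draw_seq(dist: Mapping[str, float], n: int, rng: np.random.Generator) -> list[str]:
    keys = list(dist)
    idx = rng.choice(len(keys), size=n, p=list(dist.values()))
    return [keys[i] for i in idx]


def sample_sp(params: SynthParams, rng: np.random.Generator,
              gene_id: str = "SP0001") -> tuple[SignalPeptide, dict]:
    """Draw one signal peptide with ground truth.

    Returns the :class:`SignalPeptide` (with boundaries, CDS, mature prefix,
    chromosome, location and titer filled in) and a dict of the true flags
    and feature values used by the titer model.
    """
    n_len = _draw(params.n_len_dist, rng)
    h_len = _draw(params.h_len_dist, rng)
    c_len = _draw(params.c_len_dist, rng)

    n_region = _draw_seq(params.n_residues, n_len, rng)
    n_region[0] = "M"
    h_region = _draw_seq(params.h_residues, h_len, rng)
    c_region = _draw_seq(params.c_residues, c_len, rng)

    shifted = bool(rng.random() < params.p_shifted)

    # plant the (-3,-1) site; shifted SPs get a degraded native site (the
    # small-residue rule violated at both positions), so class probabilities
    # among unshifted SPs are rescaled to keep the configured cohort-level
    # marginals.  Unshifted OTHER sites still follow the small-residue rule
    # with non-motif residues.
    if shifted:
        motif = "OTHER"
        c_region[-3] = _draw(DEGRADED_SITE, rng)
        c_region[-1] = _draw(DEGRADED_SITE, rng)
    else:
        unshifted = 1.0 - params.p_shifted
        u = rng.random()
        if u < params.p_axa / unshifted:
            motif = "AXA"
            c_region[-3] = "A"
            c_region[-1] = "A"
        elif u < (params.p_axa + params.p_vxa) / unshifted:
            motif = "VXA"
            c_region[-3] = "V"
            c_region[-1] = "A"
        else:
            motif = "OTHER"
            c_region[-3] = _draw(SMALL_MINUS3, rng)
            c_region[-1] = _draw(SMALL_MINUS1, rng)

    mature = _draw_seq(params.mature_residues, params.mature_len, rng)
    off = params.shift_plant_offset
    if shifted:
        # a complete strong context planted inside the mature prefix at
        # candidate position cleavage_pos + off: AXA triplet with a polar
        # middle, followed by the charged mature-start block
        mature[off - 3] = "A"
        mature[off - 2] = _draw(params.c_residues, rng)
        mature[off - 1] = "A"
        mature[off] = _draw(MATURE_START, rng)
        mature[off + 1] = _draw(MATURE_START, rng)
    else:
        mature[0] = _draw(MATURE_START, rng)
        mature[1] = _draw(MATURE_START, rng)

    mature_prefix = "".join(mature)
    sp_seq = "".join(n_region + h_region + c_region)
    L = len(sp_seq)

    sp_model = boosted_codon_model(
        base_codon_model(params.codon_skew), params.rare_boost,
        params.rare_quantile)
    sp_cds = _back_translate(sp_seq, sp_model, rng)

    chrom_labels = list(params.genes_per_chromosome)
    chrom_weights = np.array(
        [params.genes_per_chromosome[c] for c in chrom_labels], dtype=float)
    chromosome = chrom_labels[rng.choice(len(chrom_labels),
                                         p=chrom_weights / chrom_weights.sum())]
    location = _draw(params.location_probs, rng)

    d = RegionDecomposition(n_len=n_len, h_len=h_len, c_len=c_len)
    sp = SignalPeptide(
        gene_id=gene_id, sp_seq=sp_seq, cleavage_pos=L,
        n_end=n_len, h_end=n_len + h_len,
        chromosome=chromosome, location_label=location,
        sp_cds=sp_cds, mature_prefix=mature_prefix,
    )
    score = compound_score(sp, d).score
    charge = n_region_charge(sp, d)
    lo, hi = params.bad_band
    flags = {
        "motif": motif in ("AXA", "VXA"),
        "charge_plus1": charge == 1,
        "shifted": shifted,
        "bad_band": lo <= score <= hi,
    }
    sp.titer = simulate_titer(flags, params, rng)
    truth = {
        "true_n_len": n_len, "true_h_len": h_len, "true_c_len": c_len,
        "true_motif_class": motif, "true_shifted": shifted,
        "true_n_charge": charge, "true_compound_score": score,
        "true_flag_motif": flags["motif"],
        "true_flag_charge_plus1": flags["charge_plus1"],
        "true_flag_bad_band": flags["bad_band"],
        "true_titer_multiplier": titer_multiplier(flags, params),
    }
    return sp, truth


def titer_multiplier(flags: Mapping[str, bool], params: SynthParams) -> float:
    m = 1.0
    if flags.get("motif"):
        m *= params.mult_motif
    if flags.get("charge_plus1"):
        m *= params.mult_charge_plus1
    if flags.get("shifted"):
        m *= params.mult_shifted
    if flags.get("bad_band"):
        m *= params.mult_bad_band
    return m


def simulate_titer(flags: Mapping[str, bool], params: SynthParams,
                   rng: np.random.Generator) -> float:
    """titer = base_titer x product(active multipliers) x lognormal noise
    (median-1 noise: exp(sigma * N(0,1)))."""
    noise = math.exp(params.titer_sigma * rng.standard_normal()) \
        if params.titer_sigma > 0 else 1.0
    return params.base_titer * titer_multiplier(flags, params) * noise


def sample_cohort(params: SynthParams,
                  rng: Optional[np.random.Generator] = None
                  ) -> tuple[list[SignalPeptide], pd.DataFrame]:
    """Draw a full cohort: ``n_sps - n_duplicates`` unique SP sequences
    (uniqueness enforced by rejection sampling, 100 retries cap) plus
    ``n_duplicates`` genes re-using an already drawn SP sequence, shuffled.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_unique = params.n_sps - params.n_duplicates
    sps: list[SignalPeptide] = []
    truths: list[dict] = []
    seen: set[str] = set()
    for i in range(n_unique):
        for attempt in range(100):
            sp, truth = sample_sp(params, rng, gene_id=f"SPG{i + 1:04d}")
            if sp.sp_seq not in seen:
                break
        else:
            raise RuntimeError("could not draw a unique SP in 100 attempts")
        seen.add(sp.sp_seq)
        sps.append(sp)
        truths.append(truth)

    for j in range(params.n_duplicates):
        src = int(rng.integers(0, n_unique))
        orig, orig_truth = sps[src], truths[src]
        dup = SignalPeptide(
            gene_id=f"SPG{n_unique + j + 1:04d}", sp_seq=orig.sp_seq,
            cleavage_pos=orig.cleavage_pos, n_end=orig.n_end,
            h_end=orig.h_end, chromosome=orig.chromosome,
            location_label=orig.location_label, sp_cds=orig.sp_cds,
            mature_prefix=orig.mature_prefix,
        )
        flags = {
            "motif": orig_truth["true_flag_motif"],
            "charge_plus1": orig_truth["true_flag_charge_plus1"],
            "shifted": orig_truth["true_shifted"],
            "bad_band": orig_truth["true_flag_bad_band"],
        }
        dup.titer = simulate_titer(flags, params, rng)
        sps.append(dup)
        truths.append(dict(orig_truth))

    order = rng.permutation(len(sps))
    sps = [sps[i] for i in order]
    truths = [truths[i] for i in order]
    return sps, pd.DataFrame(truths, columns=TRUTH_COLUMNS)


def sample_orfeome(params: SynthParams,
                   rng: Optional[np.random.Generator] = None
                   ) -> list[tuple[str, str]]:
    """Background ORFeome: (header, CDS) pairs drawn from the base codon
    model over the mature-protein residue background."""
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    model = base_codon_model(params.codon_skew)
    lo, hi = params.orf_codons
    chrom_labels = list(params.genes_per_chromosome)
    chrom_weights = np.array(
        [params.genes_per_chromosome[c] for c in chrom_labels], dtype=float)
    chrom_weights /= chrom_weights.sum()
    orfs = []
    for i in range(params.n_orfs):
        n_codons = int(rng.integers(lo, hi + 1))
        protein = "M" + "".join(_draw_seq(params.mature_residues, n_codons - 1, rng))
        cds = _back_translate(protein, model, rng) + "TAA"
        chrom = chrom_labels[rng.choice(len(chrom_labels), p=chrom_weights)]
        orfs.append((f"ORF{i + 1:05d} chr={chrom}", cds))
    return orfs


def generate_cohort(params: SynthParams, out_dir) -> dict[str, Path]:
    """Write a complete synthetic data set readable by the I/O layer.

    Files: ``proteins.fasta`` (precursor = SP + mature prefix),
    ``sp_cds.fasta`` (SP coding regions), ``orfeome.fasta`` (background
    ORFs), ``annotations.tsv`` (SP table with ground-truth ``true_*``
    columns) and ``params.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    sps, truth = sample_cohort(params, rng)
    orfs = sample_orfeome(params, rng)

    paths = {
        "proteins": write_fasta(
            ((f"{sp.gene_id} chr={sp.chromosome}", sp.sp_seq + sp.mature_prefix)
             for sp in sps), out_dir / "proteins.fasta"),
        "sp_cds": write_fasta(
            ((f"{sp.gene_id} chr={sp.chromosome}", sp.sp_cds) for sp in sps),
            out_dir / "sp_cds.fasta"),
        "orfeome": write_fasta(orfs, out_dir / "orfeome.fasta"),
        "annotations": write_sp_table(sps, out_dir / "annotations.tsv",
                                      extra=truth),
    }
    params_path = out_dir / "params.json"
    with open(params_path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["params"] = params_path
    return paths
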
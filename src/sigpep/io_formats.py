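"""Readers and writers for the formats the pipeline touches.

Protein and DNA FASTA go through Biopython's :mod:`Bio.SeqIO`; annotation
tables are tab-separated text (UTF-8, ``.`` decimal) read with pandas.  All
parsers validate strictly: a malformed record is a hard error naming the
record, never a silently dropped row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger("sigpep")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
DNA_SET = frozenset("ACGT")

#: subcellular location labels accepted in annotation tables
LOCATION_LABELS = frozenset(
    {"secreted", "cell wall", "cell membrane", "membrane", "ER", "other"}
)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class SequenceRecord:
    """One protein sequence from a FASTA file.

    ``residues`` is uppercase and restricted to the 20 canonical amino
    acids; ``X`` is tolerated (annotation artifacts) but flagged with a
    logged warning and excluded from composition/hydropathy statistics
    downstream.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if len(self.residues) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")


@dataclass
class CodingRecord:
    """One coding (DNA) sequence; length must be a whole number of codons."""

    id: str
    bases: str
    chromosome: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.bases) % 3 != 0:
            raise FormatError(
                f"record {self.id!r}: CDS length {len(self.bases)} not divisible by 3"
            )


@dataclass
class SignalPeptide:
    """One annotated signal peptide.

    ``cleavage_pos`` is the 1-based index of the LAST SP residue; the mature
    protein starts at ``cleavage_pos + 1``, so the (-1) position of the
    (-3,-1) rule is ``cleavage_pos`` itself.  ``n_end`` / ``h_end`` are
    1-based indices of the last N-region and last H-region residue when the
    annotation provides the region partition.
    """

    gene_id: str
    sp_seq: str
    cleavage_pos: Optional[int] = None
    n_end: Optional[int] = None
    h_end: Optional[int] = None
    chromosome: Optional[str] = None
    location_label: Optional[str] = None
    titer: Optional[float] = None
    sp_cds: Optional[str] = None
    mature_prefix: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cleavage_pos is None:
            self.cleavage_pos = len(self.sp_seq)
        self.validate()

    def validate(self) -> None:
        if not self.gene_id:
            raise FormatError("signal peptide with empty gene_id")
        bad = _invalid_aa_positions(self.sp_seq)
        if bad:
            raise FormatError(
                f"{self.gene_id}: invalid residue {self.sp_seq[bad[0]]!r} "
                f"at position {bad[0] + 1}"
            )
        if len(self.sp_seq) != self.cleavage_pos:
            raise FormatError(
                f"{self.gene_id}: cleavage_pos {self.cleavage_pos} != "
                f"SP length {len(self.sp_seq)}"
            )
        if (self.n_end is None) != (self.h_end is None):
            raise FormatError(
                f"{self.gene_id}: n_end and h_end must be provided together"
            )
        if self.n_end is not None:
            if not (1 <= self.n_end < self.h_end < self.cleavage_pos):
                raise FormatError(
                    f"{self.gene_id}: region boundaries must satisfy "
                    f"1 <= n_end < h_end < cleavage_pos "
                    f"(got n_end={self.n_end}, h_end={self.h_end}, "
                    f"cleavage_pos={self.cleavage_pos})"
                )
        if self.titer is not None and not self.titer >= 0:
            raise FormatError(f"{self.gene_id}: negative titer {self.titer}")
        if self.location_label is not None and self.location_label not in LOCATION_LABELS:
            raise FormatError(
                f"{self.gene_id}: unknown location label {self.location_label!r}"
            )
        if self.sp_cds is not None:
            if len(self.sp_cds) != 3 * len(self.sp_seq):
                raise FormatError(
                    f"{self.gene_id}: sp_cds length {len(self.sp_cds)} != "
                    f"3 x SP length {3 * len(self.sp_seq)}"
                )
            if set(self.sp_cds) - DNA_SET:
                raise FormatError(f"{self.gene_id}: sp_cds contains non-ACGT bases")
            if translate_cds(self.sp_cds) != self.sp_seq:
                raise FormatError(
                    f"{self.gene_id}: sp_cds does not translate to sp_seq"
                )

    @property
    def has_boundaries(self) -> bool:
        return self.n_end is not None


def translate_cds(bases: str) -> str:
    """Translate an in-frame DNA string with the standard nuclear code."""
    out = []
    for i in range(0, len(bases), 3):
        codon = bases[i : i + 3]
        aa = _STANDARD_TABLE.forward_table.get(codon)
        if aa is None:
            if codon in _STANDARD_TABLE.stop_codons:
                out.append("*")
            else:
                out.append("X")
        else:
            out.append(aa)
    return "".join(out)


def _invalid_aa_positions(seq: str) -> list[int]:
    bad = []
    n_x = 0
    for i, ch in enumerate(seq):
        if ch == "X":
            n_x += 1
            continue
        if ch not in AA_SET:
            bad.append(i)
    if n_x:
        logger.warning("sequence contains %d 'X' residue(s); excluded from statistics", n_x)
    return bad


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_protein_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA; duplicate ids and non-amino-acid characters
    (other than X) are hard errors."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        for i, ch in enumerate(residues):
            if ch != "X" and ch not in AA_SET:
                raise FormatError(
                    f"record {rec.id!r}: invalid residue {ch!r} at position {i + 1}"
                )
        if "X" in residues:
            logger.warning("record %s contains 'X' residues", rec.id)
        records.append(
            SequenceRecord(id=rec.id, residues=residues, description=rec.description)
        )
    return records


def read_cds_fasta(path: str | Path) -> list[CodingRecord]:
    """Read a DNA FASTA of coding sequences.

    A ``chr=<label>`` token in the header is parsed into ``chromosome``.
    Lengths not divisible by 3 are hard errors.
    """
    records: list[CodingRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        bases = str(rec.seq).upper()
        extra = set(bases) - DNA_SET
        if extra - {"N"}:
            raise FormatError(
                f"record {rec.id!r}: non-nucleotide characters {sorted(extra - {'N'})}"
            )
        chromosome = None
        for token in rec.description.split():
            if token.startswith("chr="):
                chromosome = token[4:]
        if len(bases) % 3 != 0:
            raise FormatError(
                f"record {rec.id!r}: length {len(bases)} not divisible by 3"
            )
        records.append(CodingRecord(id=rec.id, bases=bases, chromosome=chromosome))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> Path:
    """Write (id_or_header, sequence) pairs as FASTA, 60 columns per line."""
    path = Path(path)
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


# ---------------------------------------------------------------------------
# SP annotation tables (TSV)
# ---------------------------------------------------------------------------

_SP_COLUMNS = [
    "gene_id",
    "sp_seq",
    "cleavage_pos",
    "n_end",
    "h_end",
    "chromosome",
    "location_label",
    "titer",
    "sp_cds",
    "mature_prefix",
]
_REQUIRED_SP_COLUMNS = ["gene_id", "sp_seq"]


def read_sp_table(path: str | Path) -> list[SignalPeptide]:
    """Read an SP annotation TSV (gene_id + sp_seq required, the rest
    optional); every invariant violation is a hard error with a row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_SP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    sps: list[SignalPeptide] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        get = lambda col: getattr(row, col, "") if col in df.columns else ""
        try:
            sps.append(
                SignalPeptide(
                    gene_id=get("gene_id"),
                    sp_seq=get("sp_seq").upper(),
                    cleavage_pos=_opt_int(get("cleavage_pos")),
                    n_end=_opt_int(get("n_end")),
                    h_end=_opt_int(get("h_end")),
                    chromosome=get("chromosome") or None,
                    location_label=get("location_label") or None,
                    titer=_opt_float(get("titer")),
                    sp_cds=(get("sp_cds").upper() or None),
                    mature_prefix=(get("mature_prefix").upper() or None),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path} row {row_no}: {exc}") from exc
    return sps


def write_sp_table(sps: Sequence[SignalPeptide], path: str | Path,
                   extra: Optional[pd.DataFrame] = None) -> Path:
    """Write SPs as a TSV readable by :func:`read_sp_table`.

    ``extra`` may carry additional (e.g. ground-truth) columns aligned with
    ``sps`` by position.
    """
    rows = []
    for sp in sps:
        rows.append({c: getattr(sp, c) for c in _SP_COLUMNS})
    df = pd.DataFrame(rows, columns=_SP_COLUMNS)
    if extra is not None:
        if len(extra) != len(df):
            raise ValueError("extra columns not aligned with SP list")
        df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
    # %.17g keeps doubles exact so write->read round-trips bit-for-bit
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return Path(path)


def _opt_int(value: str) -> Optional[int]:
    if value is None or value == "":
        return None
    return int(float(value))


def _opt_float(value: str) -> Optional[float]:
    if value is None or value == "":
        return None
    return float(value)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _format_float(x: object) -> object:
    if isinstance(x, (float, np.floating)):
        return float(f"{x:.6g}")
    return x


def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named table as a TSV plus one combined JSON summary.

    Column order is preserved as given; floats are formatted to six
    significant digits so repeated runs are byte-identical.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise FormatError(f"output directory {out_dir} not writable: {exc}") from exc

    paths: list[Path] = []
    summary: dict = {"tables": []}
    for name in tables:
        df = tables[name]
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths.append(path)
        summary["tables"].append(
            {"name": name, "path": path.name, "n_rows": int(len(df)),
             "columns": list(map(str, df.columns))}
        )
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_format_float)
        fh.write("\n")
    paths.append(json_path)
    return paths
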
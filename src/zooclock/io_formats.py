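"""Readers and writers for the external representations the pipeline touches.

Sequence I/O is delegated to Biopython; tabular tool outputs (pairwise
ortholog tables, domain/family annotation tables, homology hit tables,
BUSCO summaries) are tab-separated files read into typed pandas frames.
Trinity assembler identifiers (``TRINITY_DN<d>_c<d>_g<d>_i<d>[.p<d>]``)
get a small parsed model because the gene/isoform grouping they encode
drives the redundancy-reduction stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

NUCLEOTIDE_CHARS = set("ACGTN")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWY*X")


class ParseError(ValueError):
    """Raised for malformed external inputs (ids, tables, FASTA/FASTQ)."""


@dataclass(frozen=True)
class SeqRecord:
    """A sequence with the id/description split of the standard FASTA
    dialect: id is the first whitespace-delimited header token."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "nucleotide"  # or "protein"

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ParseError(f"invalid sequence id: {self.id!r}")
        if not self.residues:
            raise ParseError(f"empty sequence for id {self.id!r}")
        allowed = NUCLEOTIDE_CHARS if self.alphabet == "nucleotide" else PROTEIN_CHARS
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise ParseError(
                f"residues {sorted(bad)} in {self.id!r} not valid for "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReadPair:
    """A synchronized forward/reverse read pair with PHRED+33 qualities."""

    pair_id: str
    forward: SeqRecord
    reverse: SeqRecord
    forward_quality: str
    reverse_quality: str

    def __post_init__(self):
        if len(self.forward_quality) != len(self.forward.residues):
            raise ParseError(f"forward quality length mismatch for {self.pair_id}")
        if len(self.reverse_quality) != len(self.reverse.residues):
            raise ParseError(f"reverse quality length mismatch for {self.pair_id}")


TRINITY_RE = re.compile(
    r"^TRINITY_(DN\d+)_(c\d+)_(g\d+)_i(\d+)(?:\.p(\d+))?$"
)


@dataclass(frozen=True)
class TrinityId:
    raw: str
    gene_key: str
    isoform_index: int
    orf_index: int | None = None

    @property
    def transcript_id(self) -> str:
        """The id without any ORF suffix."""
        base = f"TRINITY_{self.gene_key}_i{self.isoform_index}"
        return base

    def format(self) -> str:
        s = self.transcript_id
        if self.orf_index is not None:
            s += f".p{self.orf_index}"
        return s


def parse_trinity_id(raw: str) -> TrinityId:
    """Parse a Trinity assembler id.

    The DN/c/g prefix identifies a gene cluster (all isoforms of one gene
    share it), ``i`` the isoform, and an optional ``.p`` suffix a
    predicted protein.
    """
    m = TRINITY_RE.match(raw)
    if m is None:
        raise ParseError(f"malformed Trinity id: {raw!r}")
    dn, c, g, iso, orf = m.groups()
    return TrinityId(
        raw=raw,
        gene_key=f"{dn}_{c}_{g}",
        isoform_index=int(iso),
        orf_index=int(orf) if orf is not None else None,
    )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _infer_alphabet(residues: str) -> str:
    return "nucleotide" if set(residues.upper()) <= NUCLEOTIDE_CHARS else "protein"


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SeqRecord]:
    """Read a FASTA file; duplicate ids and empty records are errors."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    dups: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if not residues:
            raise ParseError(f"empty FASTA record: {rec.id!r} in {path}")
        if rec.id in seen:
            dups.append(rec.id)
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SeqRecord(
                id=rec.id,
                residues=residues,
                description=desc,
                alphabet=alphabet or _infer_alphabet(residues),
            )
        )
    if dups:
        raise ParseError(f"duplicate FASTA ids in {path}: {sorted(set(dups))}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path,
                line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), line_width):
                fh.write(rec.residues[i:i + line_width] + "\n")


def read_fastq_pairs(forward_path: str | Path,
                     reverse_path: str | Path) -> list[ReadPair]:
    """Read synchronized paired FASTQ files (PHRED+33)."""
    fwd = list(SeqIO.parse(str(forward_path), "fastq"))
    rev = list(SeqIO.parse(str(reverse_path), "fastq"))
    if len(fwd) != len(rev):
        raise ParseError(
            f"desynchronized pair files: {len(fwd)} forward vs {len(rev)} reverse"
        )
    pairs = []
    for f, r in zip(fwd, rev):
        fid, rid = _strip_mate_suffix(f.id), _strip_mate_suffix(r.id)
        if fid != rid:
            raise ParseError(f"pair id mismatch: {f.id!r} vs {r.id!r}")
        pairs.append(
            ReadPair(
                pair_id=fid,
                forward=SeqRecord(id=f.id, residues=str(f.seq).upper()),
                reverse=SeqRecord(id=r.id, residues=str(r.seq).upper()),
                forward_quality=_phred_string(f),
                reverse_quality=_phred_string(r),
            )
        )
    return pairs


def write_fastq_pairs(pairs: Sequence[ReadPair], forward_path: str | Path,
                      reverse_path: str | Path) -> None:
    def _bio(rec: SeqRecord, qual: str) -> BioSeqRecord:
        out = BioSeqRecord(Seq(rec.residues), id=rec.id, description="")
        out.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        return out

    with open(forward_path, "w") as ffh, open(reverse_path, "w") as rfh:
        for p in pairs:
            SeqIO.write(_bio(p.forward, p.forward_quality), ffh, "fastq")
            SeqIO.write(_bio(p.reverse, p.reverse_quality), rfh, "fastq")


def _strip_mate_suffix(read_id: str) -> str:
    return re.sub(r"/[12]$", "", read_id)


def _phred_string(rec: BioSeqRecord) -> str:
    return "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

PAIR_TABLE_COLUMNS = ["species_a", "seq_a", "species_b", "seq_b"]
DOMAIN_TABLE_COLUMNS = ["seq_id", "db", "accession", "name", "start", "end", "evalue"]
FAMILY_TABLE_COLUMNS = ["seq_id", "family_acc"]  # subfamily_acc optional
HIT_TABLE_COLUMNS = ["query", "target", "evalue", "bitscore", "qcov", "tcov"]
BUSCO_COLUMNS = ["lineage", "complete_single", "complete_dup",
                 "fragmented", "missing", "total"]


def _read_tsv(path: str | Path, required: list[str],
              numeric: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a tab-separated table with a header row; '#'-prefixed comment
    lines are skipped; unknown columns are preserved but ignored."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    for col, typ in (numeric or {}).items():
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & (df[col] != "")]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column "
                f"{col!r} at line {bad[0] + 2}"
            )
        df[col] = converted.astype(typ)
    return df


def read_pair_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, PAIR_TABLE_COLUMNS)


def read_domain_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, DOMAIN_TABLE_COLUMNS,
                   numeric={"start": int, "end": int, "evalue": float})
    bad_db = set(df["db"]) - {"Pfam", "SMART", "CDD"}
    if bad_db:
        raise ParseError(f"{path}: unknown annotation database(s) {sorted(bad_db)}")
    return df


def read_family_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, FAMILY_TABLE_COLUMNS)
    if "subfamily_acc" not in df.columns:
        df["subfamily_acc"] = ""
    return df


def read_hit_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(
        path, HIT_TABLE_COLUMNS,
        numeric={"evalue": float, "bitscore": float, "qcov": float, "tcov": float},
    )


def read_busco_summary(path: str | Path) -> pd.DataFrame:
    return _read_tsv(
        path, BUSCO_COLUMNS,
        numeric={"complete_single": int, "complete_dup": int,
                 "fragmented": int, "missing": int, "total": int},
    )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
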
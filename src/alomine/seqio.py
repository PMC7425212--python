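"""Sequence and annotation I/O plus translation/coordinate utilities.

All genomic intervals inside the package are 0-based half-open on the
forward strand of the contig; GFF3 output converts to the on-disk 1-based
inclusive convention. Translation uses the bacterial/archaeal code
(translation table 11) with ATG/GTG/TTG accepted as initiators.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
INITIATORS = ("ATG", "GTG", "TTG")

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA = dict(_TABLE11.forward_table)
STOP_CODONS = tuple(_TABLE11.stop_codons)  # TAA, TAG, TGA

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GenomeRecord:
    """One contig/scaffold: id, uppercase nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - NT_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid nucleotide(s): {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """A protein sequence as read from / written to FASTA."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneFeature:
    """A stranded gene interval on a contig, 0-based half-open.

    ``protein`` holds the translated product (no stop residue). For a
    complete ORF whose interval includes the stop codon,
    ``len(protein) == (end - start) // 3 - 1``.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    product: str = ""
    protein: str = ""
    feature_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.kind not in ("CDS", "peptide_ORF", "gene"):
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def read_fasta(path, kind: str = "nucleotide"):
    """Read a FASTA file into GenomeRecord (nucleotide) or ProteinRecord objects.

    Raises on an empty file, on a duplicate id (named in the message) and on a
    header with no sequence.
    """
    cls = GenomeRecord if kind == "nucleotide" else ProteinRecord
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(cls(id=rec.id, seq=seq, description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable, path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def revcomp(nt_seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    nt_seq = nt_seq.upper()
    bad = set(nt_seq) - NT_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide(s) in sequence: {sorted(bad)}")
    return nt_seq.translate(_COMPLEMENT)[::-1]


def translate(nt_seq: str, start_as_met: bool = False, stop_tolerant: bool = False) -> str:
    """Translate a complete coding sequence with translation table 11.

    A trailing stop codon is accepted and emits nothing. With
    ``start_as_met`` the alternative initiators GTG/TTG at position 0 emit M.
    An internal stop raises ValueError unless ``stop_tolerant``, in which case
    it is emitted as '*'.
    """
    nt_seq = nt_seq.upper()
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} not divisible by 3")
    bad = set(nt_seq) - {"A", "C", "G", "T"}
    if bad:
        raise ValueError(f"invalid nucleotide(s) for translation: {sorted(bad)}")
    n_codons = len(nt_seq) // 3
    aa = []
    for i in range(n_codons):
        codon = nt_seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break  # trailing stop emits nothing
            if stop_tolerant:
                aa.append("*")
                continue
            raise ValueError(f"internal stop codon {codon} at codon {i}")
        residue = CODON_TO_AA[codon]
        if i == 0 and start_as_met and codon in INITIATORS:
            residue = "M"
        aa.append(residue)
    return "".join(aa)


def has_trailing_stop(nt_seq: str) -> bool:
    return len(nt_seq) >= 3 and nt_seq[-3:].upper() in STOP_CODONS


# ---------------------------------------------------------------------------
# GFF3 / TSV
# ---------------------------------------------------------------------------

def _feature_sort_key(f: GeneFeature):
    return (f.contig_id, f.start, f.end, f.strand)


def write_gff3(features: Sequence[GeneFeature], path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write features as GFF3 (1-based inclusive), deterministically sorted."""
    feats = sorted(features, key=_feature_sort_key)
    if contig_lengths is not None:
        for f in feats:
            clen = contig_lengths.get(f.contig_id)
            if clen is not None and f.end > clen:
                raise ValueError(
                    f"feature [{f.start},{f.end}) exceeds contig {f.contig_id!r} length {clen}"
                )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(feats):
            fid = f.feature_id or f"feat{i:05d}"
            attrs = [f"ID={fid}"]
            if f.product:
                attrs.append(f"product={f.product}")
            gff_type = "CDS" if f.kind == "CDS" else f.kind
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "alomine",
                        gff_type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[GeneFeature]:
    """Read the 9-column GFF3 subset written by :func:`write_gff3`."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            attr_map = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attr_map[k] = v
            feats.append(
                GeneFeature(
                    contig_id=seqid,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    kind=ftype if ftype in ("CDS", "peptide_ORF", "gene") else "CDS",
                    product=attr_map.get("product", ""),
                    feature_id=attr_map.get("ID", ""),
                )
            )
    return feats


def write_tsv(rows: Sequence[dict], path, columns: Sequence[str] | None = None) -> None:
    """Write dict rows to TSV with a header; column order is fixed by ``columns``."""
    if columns is None:
        if not rows:
            raise ValueError("columns required for empty row set")
        columns = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
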
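"""FASTA/FASTQ/BED input-output, thin wrappers over Biopython."""

from __future__ import annotations

from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import Component, ReferenceSet, SimulatedRead


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fastq(reads: Iterable[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")


def read_sequences(path) -> list[str]:
    """Read sequences from FASTQ or FASTA (by extension; FASTQ default)."""
    fmt = "fasta" if str(path).endswith((".fa", ".fasta", ".fna")) else "fastq"
    return [str(rec.seq).upper() for rec in SeqIO.parse(path, fmt)]


def read_bed(path) -> list[Component]:
    comps = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            comps.append(Component(fields[0], fields[3], int(fields[1]), int(fields[2])))
    return comps


def read_reference_set(fasta_path, bed_path, classes: dict[str, str] | None = None) -> ReferenceSet:
    """Assemble a ReferenceSet from a FASTA and a component BED.

    When the BED carries a 5th column it is used as the component class
    (rRNA/miRNA/other); an explicit ``classes`` mapping overrides it.
    """
    sequences = read_fasta(fasta_path)
    components = []
    bed_classes: dict[str, str] = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            components.append(Component(fields[0], fields[3], int(fields[1]), int(fields[2])))
            if len(fields) > 4:
                bed_classes[fields[3]] = fields[4]
    if classes:
        bed_classes.update(classes)
    return ReferenceSet(sequences=sequences, components=components, classes=bed_classes)
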
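"""Blocking-oligo design, off-target screening and in-silico blocking.

A blocking oligo is the DNA reverse complement of an abundant rRNA fragment,
carrying a 5' amino-C6 and a 3' dideoxy-C modification so that neither the
oligo nor any RNA hybridized to it can be adapter-ligated.  In-silico
blocking uses a containment proxy for hybridization: a library sequence is
removed when its full length aligns within some oligo's target sequence at
up to ``max_mm`` mismatches, which also captures the shorter subfragments of
a blocked species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._seq import reverse_complement
from .matcher import hamming_hits
from .preprocess import CollapsedLibrary
from .rrna_profile import FragmentPeak
from .synthetic_data import ReferenceSet

DEFAULT_MOD_5PRIME = "AmC6"
DEFAULT_MOD_3PRIME = "ddC"


@dataclass(frozen=True)
class BlockingOligo:
    name: str
    target_transcript: str
    target_start: int
    target_end: int
    target_sequence: str  # RNA sense, DNA alphabet
    oligo_sequence: str  # reverse complement of the target
    mod_5prime: str = DEFAULT_MOD_5PRIME
    mod_3prime: str = DEFAULT_MOD_3PRIME

    def __post_init__(self) -> None:
        if self.oligo_sequence != reverse_complement(self.target_sequence):
            raise ValueError("oligo must be the reverse complement of its target")
        if not self.mod_5prime or not self.mod_3prime:
            raise ValueError("both terminal modifications must be annotated")


@dataclass
class BlockingReport:
    """Accounting of what an oligo cocktail removed from a library."""

    blocked_per_oligo: dict[str, int] = field(default_factory=dict)
    r_before: int = 0
    r_after: int = 0
    nr_before: int = 0
    nr_after: int = 0
    composition_before: dict[str, float] = field(default_factory=dict)
    composition_after: dict[str, float] = field(default_factory=dict)
    residual_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def blocked_total(self) -> int:
        return self.r_before - self.r_after

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"R_before\t{self.r_before}\n")
            fh.write(f"R_after\t{self.r_after}\n")
            fh.write(f"NR_before\t{self.nr_before}\n")
            fh.write(f"NR_after\t{self.nr_after}\n")
            for name, n in self.blocked_per_oligo.items():
                fh.write(f"blocked_R:{name}\t{n}\n")
            for cls, frac in self.residual_fraction.items():
                fh.write(f"residual_fraction:{cls}\t{frac:.6f}\n")
            for cls, frac in self.composition_before.items():
                fh.write(f"prop_R_before:{cls}\t{frac:.6f}\n")
            for cls, frac in self.composition_after.items():
                fh.write(f"prop_R_after:{cls}\t{frac:.6f}\n")


def design_oligos(
    fragments: list[FragmentPeak],
    mods: tuple[str, str] = (DEFAULT_MOD_5PRIME, DEFAULT_MOD_3PRIME),
) -> list[BlockingOligo]:
    """One terminally modified antisense oligo per selected fragment."""
    if not fragments:
        warnings.warn("empty fragment list: designing an empty cocktail")
    oligos = []
    for frag in fragments:
        oligos.append(
            BlockingOligo(
                name=f"{frag.transcript}_{frag.start}-{frag.end}_block",
                target_transcript=frag.transcript,
                target_start=frag.start,
                target_end=frag.end,
                target_sequence=frag.sequence,
                oligo_sequence=reverse_complement(frag.sequence),
                mod_5prime=mods[0],
                mod_3prime=mods[1],
            )
        )
    return oligos


def screen_offtargets(
    oligos: list[BlockingOligo], refs: ReferenceSet, max_mm: int = 0
) -> list[str]:
    """Warnings for miRNAs that an oligo would co-block.

    A miRNA is at risk when its mature sequence lies within some oligo's
    target sequence at <= max_mm mismatches (the containment rule used by
    ``simulate_blocking``).
    """
    findings = []
    for name in refs.mirna_names:
        mirna = refs.sequences[name]
        for oligo in oligos:
            if hamming_hits(mirna, oligo.target_sequence, max_mm):
                findings.append(
                    f"miRNA {name} is contained in target of {oligo.name} "
                    f"(<= {max_mm} mismatches) and would be co-blocked"
                )
    return findings


def simulate_blocking(
    lib: CollapsedLibrary,
    oligos: list[BlockingOligo],
    max_mm: int = 2,
    refs: ReferenceSet | None = None,
    annotation_max_mm: int | None = None,
) -> tuple[CollapsedLibrary, BlockingReport]:
    """Remove every sequence contained in an oligo target at <= max_mm.

    A sequence blocked by several oligos is attributed to each of them in
    ``blocked_per_oligo`` (the totals use the union).  When ``refs`` is
    given, per-class prop_R before/after and the residual fraction of each
    targeted rRNA component are recorded via the annotation accounting.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    report = BlockingReport(
        blocked_per_oligo={o.name: 0 for o in oligos},
        r_before=lib.R,
        nr_before=lib.NR,
    )
    surviving: dict[str, int] = {}
    for seq, count in lib.counts.items():
        blocked = False
        for oligo in oligos:
            if len(seq) <= len(oligo.target_sequence) and hamming_hits(
                seq, oligo.target_sequence, max_mm
            ):
                report.blocked_per_oligo[oligo.name] += count
                blocked = True
        if not blocked:
            surviving[seq] = count
    blocked_lib = CollapsedLibrary(counts=surviving, provenance=f"{lib.provenance}+blocked")
    report.r_after = blocked_lib.R
    report.nr_after = blocked_lib.NR

    if refs is not None and blocked_lib.R > 0:
        from .matcher import annotate_library

        mm = max_mm if annotation_max_mm is None else annotation_max_mm
        before = annotate_library(lib, refs, mm).set_index("class")
        after = annotate_library(blocked_lib, refs, mm).set_index("class")
        report.composition_before = before["prop_R"].to_dict()
        report.composition_after = after["prop_R"].to_dict()
        targeted = {o.target_transcript for o in oligos}
        for comp in refs.components:
            if comp.transcript in targeted and refs.classes.get(comp.label) == "rRNA":
                if comp.label in after.index:
                    report.residual_fraction[comp.label] = float(after.loc[comp.label, "prop_R"])
    return blocked_lib, report


def write_oligos_tsv(oligos: list[BlockingOligo], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\ttarget_transcript\tstart\tend\ttarget_sequence\toligo_sequence\tmod_5prime\tmod_3prime\n")
        for o in oligos:
            fh.write(
                f"{o.name}\t{o.target_transcript}\t{o.target_start}\t{o.target_end}\t"
                f"{o.target_sequence}\t{o.oligo_sequence}\t{o.mod_5prime}\t{o.mod_3prime}\n"
            )


def write_oligos_fasta(oligos: list[BlockingOligo], path) -> None:
    with open(path, "w") as fh:
        for o in oligos:
            fh.write(f">{o.name} 5'-{o.mod_5prime} 3'-{o.mod_3prime}\n{o.oligo_sequence}\n")


def read_oligos_tsv(path) -> list[BlockingOligo]:
    oligos = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            oligos.append(
                BlockingOligo(
                    name=row["name"],
                    target_transcript=row["target_transcript"],
                    target_start=int(row["start"]),
                    target_end=int(row["end"]),
                    target_sequence=row["target_sequence"],
                    oligo_sequence=row["oligo_sequence"],
                    mod_5prime=row["mod_5prime"],
                    mod_3prime=row["mod_3prime"],
                )
            )
    return oligos
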
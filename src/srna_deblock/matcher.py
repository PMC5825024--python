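"""Full-length, gap-free matching of short queries with bounded mismatches.

A query of length L hits a reference at position p when the Hamming distance
between the query and ``reference[p:p+L]`` is at most ``max_mm`` — no
partial or gapped alignments.  The scan is vectorized: the reference is
viewed as a byte array and all L-length windows are compared at once, which
at desk scale (references of a few kb, thousands of distinct queries)
outperforms an index without extra machinery.

``annotate_library`` turns hits into the R/NR/complexity/proportion
accounting used for contamination diagnosis: a distinct sequence is
*incident* with a class when it has at least one qualifying hit, and class
incidences are independent (one sequence may count toward genome, rRNA and
miRNA simultaneously).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode, is_dna, reverse_complement
from .preprocess import CollapsedLibrary, complexity_ratio
from .synthetic_data import FIVE_S_NAME, GENOME_NAME, PRE_RRNA_NAME, ReferenceSet

#: Column order of the annotation summary, mirroring the contamination tables.
ANNOTATION_CLASSES = ("genome", "rRNA", "18S", "5.8S", "2S", "28S", "5S", "miRNA")


@dataclass(frozen=True)
class Hit:
    query: str
    reference: str
    start: int
    strand: str
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.query)


def hamming_hits(query: str, reference: str, max_mm: int = 0) -> list[tuple[int, int]]:
    """All (start, mismatches) where the full query aligns at <= max_mm.

    Positions are 0-based on the forward strand of ``reference``.
    """
    L, n = len(query), len(reference)
    if L == 0 or L > n:
        return []
    windows = sliding_window_view(encode(reference), L)
    mm = (windows != encode(query)).sum(axis=1)
    starts = np.nonzero(mm <= max_mm)[0]
    return [(int(p), int(mm[p])) for p in starts]


def match(
    query: str,
    refs: ReferenceSet,
    max_mm: int = 0,
    strands: str = "both",
    reference_names: list[str] | None = None,
) -> list[Hit]:
    """Hits of ``query`` across the reference set.

    ``strands='both'`` also reports minus-strand hits (the window equals the
    reverse complement of the query); ``'sense'`` restricts to the forward
    strand, appropriate for transcript references.
    """
    if not is_dna(query):
        raise ValueError("query must be non-empty A/C/G/T (ambiguous reads are filtered upstream)")
    if not 0 <= max_mm <= 2:
        raise ValueError("max_mm must be 0, 1 or 2")
    if strands not in ("both", "sense"):
        raise ValueError("strands must be 'both' or 'sense'")
    names = reference_names if reference_names is not None else list(refs.sequences)
    hits: list[Hit] = []
    rc = reverse_complement(query) if strands == "both" else None
    for name in names:
        ref_seq = refs.sequences[name]
        for start, mm in hamming_hits(query, ref_seq, max_mm):
            hits.append(Hit(query, name, start, "+", mm))
        if rc is not None:
            for start, mm in hamming_hits(rc, ref_seq, max_mm):
                hits.append(Hit(query, name, start, "-", mm))
    return hits


def _incident_components(
    query: str, refs: ReferenceSet, max_mm: int, component_labels: tuple[str, ...]
) -> set[str]:
    """rRNA component labels whose interval overlaps >= 1 nt with any sense hit."""
    incident: set[str] = set()
    by_transcript: dict[str, list[tuple[str, int, int]]] = {}
    for comp in refs.components:
        if comp.label in component_labels:
            by_transcript.setdefault(comp.transcript, []).append((comp.label, comp.start, comp.end))
    for transcript, comps in by_transcript.items():
        seq = refs.sequences[transcript]
        for start, _ in hamming_hits(query, seq, max_mm):
            end = start + len(query)
            for label, cstart, cend in comps:
                if start < cend and cstart < end:
                    incident.add(label)
    return incident


def annotate_library(
    lib: CollapsedLibrary, refs: ReferenceSet, max_mm: int = 0
) -> pd.DataFrame:
    """Per-class R/NR/complexity/proportion accounting.

    Classes: ``genome`` (both strands of the genome surrogate), ``rRNA``
    (sense hits on any rRNA transcript), the pre-rRNA components
    ``18S/5.8S/2S/28S`` (sense hit overlapping the component interval by
    >= 1 nt; hits entirely within spacers count toward rRNA only), ``5S``
    and ``miRNA`` (sense containment within a mature miRNA).  Proportions
    are relative to the library's total valid R and NR.
    """
    total_r, total_nr = lib.R, lib.NR
    if total_r == 0:
        raise ValueError("cannot annotate an empty library")

    has_genome = GENOME_NAME in refs.sequences
    rrna_names = refs.rrna_transcripts
    mirna_names = refs.mirna_names
    component_labels = tuple(
        lab for lab in ("18S", "5.8S", "2S", "28S", "5S") if any(c.label == lab for c in refs.components)
    )
    for cls, present in (("genome", has_genome), ("rRNA", bool(rrna_names)), ("miRNA", bool(mirna_names))):
        if not present:
            warnings.warn(f"reference set lacks {cls} sequences; class omitted from summary")

    acc = {cls: [0, 0] for cls in ANNOTATION_CLASSES}  # class -> [R, NR]
    for seq, count in lib.counts.items():
        incident: set[str] = set()
        if has_genome and match(seq, refs, max_mm, "both", [GENOME_NAME]):
            incident.add("genome")
        if rrna_names and any(
            hamming_hits(seq, refs.sequences[t], max_mm) for t in rrna_names
        ):
            incident.add("rRNA")
        if "rRNA" in incident:
            incident |= _incident_components(seq, refs, max_mm, component_labels)
        if mirna_names and any(
            hamming_hits(seq, refs.sequences[m], max_mm) for m in mirna_names
        ):
            incident.add("miRNA")
        for cls in incident:
            acc[cls][0] += count
            acc[cls][1] += 1

    rows = []
    for cls in ANNOTATION_CLASSES:
        if cls == "genome" and not has_genome:
            continue
        if cls == "rRNA" and not rrna_names:
            continue
        if cls == "miRNA" and not mirna_names:
            continue
        if cls in ("18S", "5.8S", "2S", "28S", "5S") and cls not in component_labels:
            continue
        r, nr = acc[cls]
        rows.append(
            {
                "class": cls,
                "R": r,
                "NR": nr,
                "complexity": complexity_ratio(nr, r) if r else float("nan"),
                "prop_R": r / total_r,
                "prop_NR": nr / total_nr,
            }
        )
    return pd.DataFrame(rows)
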
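"""Synthetic references and raw sRNA-seq libraries with known ground truth.

Emulates the read populations seen in Drosophila reproductive-tissue
small-RNA libraries: a dominant intact 30 nt 2S rRNA, discrete terminal
fragments of the 5.8S/28S (and the 3' end of 5S), a diffuse rRNA degradation
background, and a miRNA population with a 22 nt modal length and long-tailed
abundances.  Reads carry the HD-adapter architecture (4 random nt on each
side of the insert, then the 3' adapter) and optional per-base substitution
error, so the whole downstream pipeline is testable without any download.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._seq import ADAPTER_SEED_LENGTH, DEFAULT_ADAPTER, DNA_ALPHABET, random_dna


class ConfigurationError(ValueError):
    """Raised when a reference or simulation configuration is inconsistent."""


class Component(NamedTuple):
    """Annotated interval (0-based, half-open) on a reference transcript."""

    transcript: str
    label: str
    start: int
    end: int


#: Order of pieces along the polycistronic ribosomal precursor.
PRE_RRNA_LAYOUT = ("ETS", "18S", "ITS1", "5.8S", "ITS2a", "2S", "ITS2b", "28S")
SPACER_LABELS = frozenset({"ETS", "ITS1", "ITS2a", "ITS2b"})

PRE_RRNA_NAME = "pre_rRNA"
FIVE_S_NAME = "5S_rRNA"
GENOME_NAME = "genome"

DEFAULT_COMPONENT_LENGTHS = {"18S": 200, "5.8S": 123, "2S": 30, "28S": 400}

#: Fixed terminal-fragment species: label -> (transcript component, end, length).
DEFAULT_TERMINAL_FRAGMENTS = {
    "5.8S_5p": ("5.8S", "5p", 25),
    "5.8S_3p": ("5.8S", "3p", 28),
    "28S_5p": ("28S", "5p", 30),
    "28S_3p": ("28S", "3p", 27),
    "5S_3p": ("5S", "3p", 24),
}

DEFAULT_CLASS_FRACTIONS = {
    "2S": 0.82,
    "5.8S_5p": 0.011,
    "5.8S_3p": 0.011,
    "28S_5p": 0.011,
    "28S_3p": 0.011,
    "5S_3p": 0.011,
    "degradation": 0.04,
    "miRNA": 0.075,
    "unannotated": 0.01,
}


@dataclass(frozen=True)
class ReferenceSet:
    """Named reference sequences plus component intervals and their classes.

    ``sequences`` holds the genome surrogate, the pre-rRNA transcript, the 5S
    transcript and one entry per mature miRNA.  ``components`` are 0-based
    half-open intervals on those sequences; ``classes`` maps each component
    label to ``rRNA``, ``miRNA`` or ``other``.
    """

    sequences: dict[str, str]
    components: list[Component]
    classes: dict[str, str]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for comp in self.components:
            if comp.transcript not in self.sequences:
                raise ConfigurationError(f"component on unknown transcript {comp.transcript!r}")
            if not (0 <= comp.start < comp.end <= len(self.sequences[comp.transcript])):
                raise ConfigurationError(f"component {comp.label!r} outside its transcript")
            key = (comp.transcript, comp.label)
            if key in seen:
                raise ConfigurationError(f"duplicate component label {comp.label!r} on {comp.transcript!r}")
            seen.add(key)
            if comp.label == "2S" and comp.end - comp.start != 30:
                raise ConfigurationError("2S component must be exactly 30 nt")

    # -- convenience lookups -------------------------------------------------
    def component(self, label: str, transcript: str | None = None) -> Component:
        for comp in self.components:
            if comp.label == label and (transcript is None or comp.transcript == transcript):
                return comp
        raise KeyError(label)

    def component_sequence(self, label: str, transcript: str | None = None) -> str:
        comp = self.component(label, transcript)
        return self.sequences[comp.transcript][comp.start:comp.end]

    @property
    def rrna_transcripts(self) -> list[str]:
        names: list[str] = []
        for comp in self.components:
            if self.classes.get(comp.label) == "rRNA" and comp.transcript not in names:
                if comp.transcript != GENOME_NAME:
                    names.append(comp.transcript)
        return names

    @property
    def mirna_names(self) -> list[str]:
        return [
            comp.transcript
            for comp in self.components
            if self.classes.get(comp.label) == "miRNA" and comp.transcript == comp.label
        ]

    # -- serialization -------------------------------------------------------
    def write_fasta(self, path) -> None:
        from . import io as _io

        _io.write_fasta(self.sequences, path)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for comp in self.components:
                cls = self.classes.get(comp.label, "other")
                fh.write(f"{comp.transcript}\t{comp.start}\t{comp.end}\t{comp.label}\t{cls}\n")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated sequencing run.

    ``class_fractions`` gives the proportion of reads whose insert is drawn
    from each population; keys are ``2S``, the terminal-fragment species
    (``5.8S_5p`` ... ``5S_3p``), ``degradation``, ``miRNA`` and
    ``unannotated``.  All randomness flows from ``seed``.
    """

    seed: int
    n_reads: int
    read_length: int = 50
    class_fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    n_mirnas: int = 50
    mirna_abundance_shape: tuple[float, float] = (0.0, 1.5)  # log-normal mean, sd
    mirna_length_probs: dict[int, float] = field(default_factory=lambda: {21: 0.2, 22: 0.6, 23: 0.2})
    error_rate: float = 0.0
    adapter_sequence: str = DEFAULT_ADAPTER
    hd_signature_length: int = 4
    degradation_length_range: tuple[int, int] = (20, 35)

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"class_fractions sum to {total}, expected 1")
        if any(f < 0 or f > 1 for f in self.class_fractions.values()):
            raise ConfigurationError("class fractions must lie in [0, 1]")
        if not math.isclose(sum(self.mirna_length_probs.values()), 1.0, abs_tol=1e-9):
            raise ConfigurationError("mirna_length_probs must sum to 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ConfigurationError("error_rate must lie in [0, 1]")
        if self.n_reads < 0 or self.read_length <= 0:
            raise ConfigurationError("n_reads and read_length must be positive")


class SimulatedRead(NamedTuple):
    read_id: str
    sequence: str
    quality: str


class FragmentTruth(NamedTuple):
    """A planted fixed fragment species and its expected redundant count."""

    label: str
    sequence: str
    transcript: str
    start: int
    end: int
    expected_count: float


class ReadTruth(NamedTuple):
    read_id: str
    label: str
    insert: str
    transcript: str
    start: int
    end: int


@dataclass
class GroundTruth:
    """Per-read true labels plus the planted fragment catalogue."""

    reads: list[ReadTruth]
    expected_fractions: dict[str, float]
    fragments: list[FragmentTruth]

    def insert_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.reads:
            counts[rec.insert] = counts.get(rec.insert, 0) + 1
        return counts

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.reads:
            counts[rec.label] = counts.get(rec.label, 0) + 1
        return counts

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tclass\tinsert\ttranscript\tstart\tend\n")
            for rec in self.reads:
                fh.write("\t".join(str(x) for x in rec) + "\n")


def make_references(
    seed: int,
    component_lengths: dict[str, int] | None = None,
    spacer_length: int = 50,
    n_mirnas: int = 50,
    five_s_length: int = 120,
    mirna_length: int = 23,
    background_length: int = 2000,
) -> ReferenceSet:
    """Build a scaled-down reference set with the pre-rRNA architecture.

    The pre-rRNA transcript carries, in order, ETS-18S-ITS1-5.8S-ITS2a-2S-
    ITS2b-28S; the 5S rRNA is a separate transcript; ``n_mirnas`` mature
    miRNAs are generated and embedded, together with both rRNA transcripts,
    in a random-background genome surrogate.  Deterministic under ``seed``.
    """
    lengths = dict(DEFAULT_COMPONENT_LENGTHS)
    if component_lengths:
        lengths.update(component_lengths)
    for label in ("18S", "5.8S", "2S", "28S"):
        if label not in lengths:
            raise ConfigurationError(f"component_lengths missing {label}")
    if lengths["2S"] != 30:
        raise ConfigurationError("2S rRNA must be exactly 30 nt")

    adapter_seed = DEFAULT_ADAPTER[:ADAPTER_SEED_LENGTH]
    rng = np.random.default_rng(seed)

    for _ in range(50):  # junctions may recreate the adapter seed; rebuild if so
        pieces: list[str] = []
        components: list[Component] = []
        pos = 0
        for label in PRE_RRNA_LAYOUT:
            n = spacer_length if label in SPACER_LABELS else lengths[label]
            pieces.append(random_dna(rng, n, forbidden=adapter_seed))
            components.append(Component(PRE_RRNA_NAME, label, pos, pos + n))
            pos += n
        pre_rrna = "".join(pieces)

        five_s = random_dna(rng, five_s_length, forbidden=adapter_seed)
        components.append(Component(FIVE_S_NAME, "5S", 0, five_s_length))

        mirnas = {
            f"mir-{i + 1:03d}": random_dna(rng, mirna_length, forbidden=adapter_seed)
            for i in range(n_mirnas)
        }
        for name, seq in mirnas.items():
            components.append(Component(name, name, 0, len(seq)))

        genome_parts = [random_dna(rng, background_length // 2, forbidden=adapter_seed), pre_rrna]
        for seq in [five_s, *mirnas.values()]:
            genome_parts.append(random_dna(rng, 20, forbidden=adapter_seed))
            genome_parts.append(seq)
        genome_parts.append(random_dna(rng, background_length // 2, forbidden=adapter_seed))
        genome = "".join(genome_parts)

        sequences = {GENOME_NAME: genome, PRE_RRNA_NAME: pre_rrna, FIVE_S_NAME: five_s, **mirnas}
        if not any(adapter_seed in s for s in sequences.values()):
            break
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("failed to build adapter-free references")

    classes = {label: ("other" if label in SPACER_LABELS else "rRNA") for label in PRE_RRNA_LAYOUT}
    classes["5S"] = "rRNA"
    classes.update({name: "miRNA" for name in mirnas})
    return ReferenceSet(sequences=sequences, components=components, classes=classes)


def _fragment_catalogue(config: SimulationConfig, refs: ReferenceSet) -> dict[str, FragmentTruth]:
    """Fixed fragment species (2S + terminal fragments) active in this run."""
    catalogue: dict[str, FragmentTruth] = {}
    for label, frac in config.class_fractions.items():
        if label == "2S":
            comp = refs.component("2S")
            seq = refs.component_sequence("2S")
            catalogue[label] = FragmentTruth(label, seq, comp.transcript, comp.start, comp.end, frac * config.n_reads)
        elif label in DEFAULT_TERMINAL_FRAGMENTS:
            comp_label, which_end, frag_len = DEFAULT_TERMINAL_FRAGMENTS[label]
            comp = refs.component(comp_label)
            if which_end == "5p":
                start, end = comp.start, comp.start + frag_len
            else:
                start, end = comp.end - frag_len, comp.end
            seq = refs.sequences[comp.transcript][start:end]
            catalogue[label] = FragmentTruth(label, seq, comp.transcript, start, end, frac * config.n_reads)
    return catalogue


def simulate_library(
    config: SimulationConfig, refs: ReferenceSet
) -> tuple[list[SimulatedRead], GroundTruth]:
    """Draw reads per ``class_fractions`` and assemble HD-adapter reads.

    Each read is ``sig5 + insert + sig3 + adapter`` truncated to
    ``read_length``, with per-base substitution errors applied last.  HD
    signatures are resampled if they would create a spurious adapter-seed
    match upstream of the true adapter start, keeping leftmost-seed trimming
    exact on error-free reads.  Returns the reads and a per-read ground truth.
    """
    rng = np.random.default_rng(config.seed)
    labels = list(config.class_fractions)
    probs = np.array([config.class_fractions[c] for c in labels])
    label_idx = rng.choice(len(labels), size=config.n_reads, p=probs)

    catalogue = _fragment_catalogue(config, refs)
    pre_rrna = refs.sequences.get(PRE_RRNA_NAME, "")
    mirna_names = refs.mirna_names
    if "miRNA" in config.class_fractions and config.class_fractions["miRNA"] > 0 and not mirna_names:
        raise ConfigurationError("miRNA fraction requested but reference set has no miRNAs")
    mu, sigma = config.mirna_abundance_shape
    mirna_weights = rng.lognormal(mu, sigma, size=len(mirna_names)) if mirna_names else np.array([])
    if mirna_weights.size:
        mirna_weights = mirna_weights / mirna_weights.sum()
    mirna_lengths = sorted(config.mirna_length_probs)
    mirna_len_probs = np.array([config.mirna_length_probs[k] for k in mirna_lengths])

    adapter_seed = config.adapter_sequence[:ADAPTER_SEED_LENGTH]
    bases = np.array(list(DNA_ALPHABET))
    sig = config.hd_signature_length

    reads: list[SimulatedRead] = []
    truths: list[ReadTruth] = []
    for i, li in enumerate(label_idx):
        label = labels[li]
        if label in catalogue:
            frag = catalogue[label]
            insert, transcript, start, end = frag.sequence, frag.transcript, frag.start, frag.end
        elif label == "degradation":
            lo, hi = config.degradation_length_range
            flen = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(pre_rrna) - flen + 1))
            end = start + flen
            insert, transcript = pre_rrna[start:end], PRE_RRNA_NAME
        elif label == "miRNA":
            name = mirna_names[int(rng.choice(len(mirna_names), p=mirna_weights))]
            full = refs.sequences[name]
            flen = min(int(rng.choice(mirna_lengths, p=mirna_len_probs)), len(full))
            insert, transcript, start, end = full[:flen], name, 0, flen
        elif label == "unannotated":
            insert = random_dna(rng, 22, forbidden=adapter_seed)
            transcript, start, end = ".", 0, 22
        else:
            raise ConfigurationError(f"unknown read class {label!r}")

        adapter_at = 2 * sig + len(insert)
        for _ in range(100):
            sig5 = "".join(rng.choice(bases, size=sig)) if sig else ""
            sig3 = "".join(rng.choice(bases, size=sig)) if sig else ""
            assembled = sig5 + insert + sig3 + config.adapter_sequence
            if assembled.find(adapter_seed) == adapter_at:
                break
        read_seq = assembled[: config.read_length]

        if config.error_rate > 0:
            arr = np.array(list(read_seq))
            hit = rng.random(arr.size) < config.error_rate
            if hit.any():
                for j in np.nonzero(hit)[0]:
                    choices = [b for b in DNA_ALPHABET if b != arr[j]]
                    arr[j] = choices[int(rng.integers(0, 3))]
                read_seq = "".join(arr)

        rid = f"read_{i:07d}"
        reads.append(SimulatedRead(rid, read_seq, "I" * len(read_seq)))
        truths.append(ReadTruth(rid, label, insert, transcript, start, end))

    ground_truth = GroundTruth(
        reads=truths,
        expected_fractions=dict(config.class_fractions),
        fragments=sorted(catalogue.values(), key=lambda f: -f.expected_count),
    )
    return reads, ground_truth


def replace(config: SimulationConfig, **changes) -> SimulationConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return dataclasses.replace(config, **changes)
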
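"""Raw reads -> collapsed library of valid inserts, plus QC summaries.

The trimming rules are deliberately strict and simple: reads containing any
ambiguous base are dropped; the 3' adapter is located by a perfect match of
its first 7 nt (leftmost occurrence wins); the HD signatures (4 nt at each
end of the insert) are then removed; and only inserts within the configured
valid length range are kept.  Valid inserts are collapsed from redundant (R,
total reads) to non-redundant (NR, distinct sequences) form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Iterator

from ._seq import ADAPTER_SEED_LENGTH, DEFAULT_ADAPTER, is_dna

DEFAULT_MIN_INSERT = 18
DEFAULT_MAX_INSERT = 36


@dataclass
class TrimReport:
    """Read accounting across the preprocessing stages."""

    n_input: int = 0
    n_with_N: int = 0
    n_adapter_trimmed: int = 0
    n_valid_inserts: int = 0

    @property
    def fraction_adapter_trimmed(self) -> float:
        kept = self.n_input - self.n_with_N
        return self.n_adapter_trimmed / kept if kept else 0.0

    @property
    def fraction_valid(self) -> float:
        return self.n_valid_inserts / self.n_input if self.n_input else 0.0

    def validate(self) -> None:
        if not 0 <= self.n_valid_inserts <= self.n_adapter_trimmed <= self.n_input - self.n_with_N:
            raise ValueError("trim counts are not nested")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"n_input\t{self.n_input}\n")
            fh.write(f"n_with_N\t{self.n_with_N}\n")
            fh.write(f"n_adapter_trimmed\t{self.n_adapter_trimmed}\n")
            fh.write(f"n_valid_inserts\t{self.n_valid_inserts}\n")
            fh.write(f"fraction_adapter_trimmed\t{self.fraction_adapter_trimmed:.4f}\n")
            fh.write(f"fraction_valid\t{self.fraction_valid:.4f}\n")


@dataclass
class CollapsedLibrary:
    """Non-redundant sequence -> redundant count map.

    R is the redundant total (sum of counts), NR the number of distinct
    sequences; complexity is NR/R.
    """

    counts: dict[str, int] = field(default_factory=dict)
    provenance: str = ""

    @property
    def R(self) -> int:
        return sum(self.counts.values())

    @property
    def NR(self) -> int:
        return len(self.counts)

    def expand(self) -> Iterator[str]:
        for seq, n in self.counts.items():
            yield from (seq for _ in range(n))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence\tcount\n")
            for seq, n in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{seq}\t{n}\n")

    def write_fasta(self, path) -> None:
        """Count-bearing FASTA (``>seq<rank>_x<count>`` header dialect)."""
        with open(path, "w") as fh:
            for rank, (seq, n) in enumerate(
                sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])), start=1
            ):
                fh.write(f">seq{rank}_x{n}\n{seq}\n")

    @classmethod
    def from_tsv(cls, path, provenance: str = "tsv") -> "CollapsedLibrary":
        counts: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("sequence"):
                fh.seek(0)
            for line in fh:
                seq, n = line.split("\t")
                counts[seq] = counts.get(seq, 0) + int(n)
        return cls(counts=counts, provenance=provenance)


def filter_ambiguous(reads: Iterable[str]) -> tuple[list[str], int]:
    """Drop reads containing any character outside A/C/G/T; return kept, n dropped."""
    kept, dropped = [], 0
    for read in reads:
        if is_dna(read):
            kept.append(read)
        else:
            dropped += 1
    return kept, dropped


def trim_adapter(read: str, adapter_prefix: str = DEFAULT_ADAPTER[:ADAPTER_SEED_LENGTH]) -> str | None:
    """Subsequence strictly before the leftmost exact adapter-seed match.

    Returns ``None`` when the 7-nt seed is absent (the read is discarded
    downstream); an occurrence at position 0 yields the empty string, which
    the length filter later rejects.
    """
    if len(adapter_prefix) != ADAPTER_SEED_LENGTH:
        raise ValueError("adapter prefix must be 7 nt")
    pos = read.find(adapter_prefix)
    return None if pos < 0 else read[:pos]


def trim_hd_signature(
    insert_with_sigs: str,
    sig_len: int = 4,
    min_len: int = DEFAULT_MIN_INSERT,
    max_len: int = DEFAULT_MAX_INSERT,
) -> tuple[str, str, str] | None:
    """Strip ``sig_len`` nt from each end; ``None`` if the core is invalid.

    Returns ``(core, sig5, sig3)``; invalid when the remaining core length
    falls outside ``[min_len, max_len]``.
    """
    if sig_len < 0:
        raise ValueError("sig_len must be >= 0")
    if len(insert_with_sigs) <= 2 * sig_len:
        return None
    core = insert_with_sigs[sig_len : len(insert_with_sigs) - sig_len]
    if not min_len <= len(core) <= max_len:
        return None
    sig5 = insert_with_sigs[:sig_len]
    sig3 = insert_with_sigs[len(insert_with_sigs) - sig_len :]
    return core, sig5, sig3


def collapse(inserts: Iterable[str], provenance: str = "collapsed") -> CollapsedLibrary:
    """Exact-sequence multiset collapse to non-redundant form."""
    return CollapsedLibrary(counts=dict(Counter(inserts)), provenance=provenance)


def complexity(lib: CollapsedLibrary) -> float:
    """Library complexity NR/R (in (0, 1]); low values mean few dominant reads."""
    if lib.R == 0:
        raise ValueError("complexity undefined for an empty library")
    return lib.NR / lib.R


def complexity_ratio(nr: int, r: int) -> float:
    """NR/R from totals alone (used when only the totals are known)."""
    if r <= 0:
        raise ValueError("complexity undefined for R <= 0")
    return nr / r


def size_class_distribution(lib: CollapsedLibrary):
    """Per-length redundant and non-redundant counts as a DataFrame.

    Conserves totals: the R column sums to lib.R and NR to lib.NR.
    """
    import pandas as pd

    per_len_r: Counter[int] = Counter()
    per_len_nr: Counter[int] = Counter()
    for seq, n in lib.counts.items():
        per_len_r[len(seq)] += n
        per_len_nr[len(seq)] += 1
    if not per_len_r:
        return pd.DataFrame({"length": [], "R": [], "NR": []}).astype(int)
    lengths = range(min(per_len_r), max(per_len_r) + 1)
    return pd.DataFrame(
        {
            "length": list(lengths),
            "R": [per_len_r.get(n, 0) for n in lengths],
            "NR": [per_len_nr.get(n, 0) for n in lengths],
        }
    )


def preprocess_reads(
    reads: Iterable[str],
    adapter_prefix: str = DEFAULT_ADAPTER[:ADAPTER_SEED_LENGTH],
    sig_len: int = 4,
    min_len: int = DEFAULT_MIN_INSERT,
    max_len: int = DEFAULT_MAX_INSERT,
) -> tuple[CollapsedLibrary, TrimReport]:
    """Full preprocessing pipeline: N-filter, adapter trim, HD trim, collapse."""
    report = TrimReport()
    inserts: list[str] = []
    for read in reads:
        report.n_input += 1
        if not is_dna(read):
            report.n_with_N += 1
            continue
        with_sigs = trim_adapter(read, adapter_prefix)
        if with_sigs is None:
            continue
        report.n_adapter_trimmed += 1
        trimmed = trim_hd_signature(with_sigs, sig_len, min_len, max_len)
        if trimmed is None:
            continue
        report.n_valid_inserts += 1
        inserts.append(trimmed[0])
    report.validate()
    return collapse(inserts, provenance="preprocessed"), report
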
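"""Per-position presence profiles and abundant-fragment discovery.

A presence profile sums, at every transcript position, the unnormalized
redundant abundances of all library sequences that match the transcript
perfectly and cover that position (linear scale).  Profiles localize the
discrete rRNA fragments that dominate contaminated libraries; the most
abundant of them become blocking-oligo targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matcher import hamming_hits
from .preprocess import CollapsedLibrary


@dataclass
class PresenceProfile:
    transcript: str
    values: np.ndarray  # length == transcript length, linear scale

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tpresence\n")
            for pos, val in enumerate(self.values):
                fh.write(f"{pos}\t{int(val)}\n")


@dataclass(frozen=True)
class FragmentPeak:
    """A discrete, highly abundant fragment matching the transcript exactly."""

    sequence: str
    transcript: str
    start: int
    end: int
    abundance: int
    rank: int


def presence_profile(
    lib: CollapsedLibrary, transcript: str, name: str = "transcript"
) -> PresenceProfile:
    """Sum redundant abundance over every position of every perfect hit.

    Every perfect hit contributes (all-hits policy): a sequence occurring at
    two loci adds its count at both, so the profile total always equals
    sum(count * length * number_of_hits) over the library.
    """
    values = np.zeros(len(transcript), dtype=np.int64)
    for seq, count in lib.counts.items():
        for start, _ in hamming_hits(seq, transcript, max_mm=0):
            values[start : start + len(seq)] += count
    return PresenceProfile(transcript=name, values=values)


def find_abundant_fragments(
    lib: CollapsedLibrary,
    transcript: str,
    top_n: int = 7,
    min_abundance: int = 1,
    len_range: tuple[int, int] = (20, 35),
    max_overlap_frac: float = 0.5,
    name: str = "transcript",
) -> list[FragmentPeak]:
    """Top-N distinct fragments with perfect hits, ranked by abundance.

    Candidates are distinct library sequences with at least one perfect hit
    on the transcript, length within ``len_range`` and abundance at least
    ``min_abundance``; each is placed at its leftmost hit.  After ranking
    (abundance descending, then position, then sequence), a candidate whose
    interval overlaps a retained higher-ranked interval by more than
    ``max_overlap_frac`` of the shorter interval is suppressed, so near-
    duplicate targets yield a single oligo.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    lo, hi = len_range
    candidates: list[tuple[int, int, str]] = []  # (abundance, start, seq)
    for seq, count in lib.counts.items():
        if not lo <= len(seq) <= hi or count < min_abundance:
            continue
        hits = hamming_hits(seq, transcript, max_mm=0)
        if hits:
            candidates.append((count, hits[0][0], seq))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    kept: list[FragmentPeak] = []
    for count, start, seq in candidates:
        end = start + len(seq)
        suppressed = False
        for peak in kept:
            overlap = min(end, peak.end) - max(start, peak.start)
            shorter = min(end - start, peak.end - peak.start)
            if overlap > max_overlap_frac * shorter:
                suppressed = True
                break
        if not suppressed:
            kept.append(FragmentPeak(seq, name, start, end, count, rank=len(kept) + 1))
        if len(kept) == top_n:
            break
    if not kept:
        warnings.warn("no qualifying fragments found")
    return kept


def terminal_fraction(
    profile: PresenceProfile, component: tuple[int, int], window: int
) -> tuple[float, float]:
    """Fraction of a component's profile mass within ``window`` nt of each end.

    Returns ``(fraction_5prime, fraction_3prime)``; NaNs when the component
    carries no mass.
    """
    start, end = component
    if window > (end - start) / 2:
        raise ValueError("window exceeds half the component length")
    mass = profile.values[start:end].astype(float)
    total = mass.sum()
    if total == 0:
        return float("nan"), float("nan")
    return float(mass[:window].sum() / total), float(mass[-window:].sum() / total)


def write_fragments_tsv(fragments: list[FragmentPeak], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\ttranscript\tstart\tend\tlength\tsequence\tabundance\n")
        for f in fragments:
            fh.write(
                f"{f.rank}\t{f.transcript}\t{f.start}\t{f.end}\t{f.end - f.start}\t{f.sequence}\t{f.abundance}\n"
            )
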
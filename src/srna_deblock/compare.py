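"""Concordance between two collapsed libraries (blocked vs non-blocked).

Abundances are normalized to reads per million (RPM) of each library's
retained denominator set (by default everything except rRNA-incident
sequences, which blocking is supposed to remove), then compared with MA
representations and Pearson/Spearman/Kendall correlation curves across
abundance thresholds.  Agreement of the curves near 1 is the computational
signature that blocking preserved the underlying sRNA population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matcher import hamming_hits
from .preprocess import CollapsedLibrary
from .synthetic_data import ReferenceSet


@dataclass
class ComparisonResult:
    ma: pd.DataFrame  # columns: sequence, A, M
    curve: pd.DataFrame  # columns: threshold, pcc, scc, kcc, n_sequences


def _incident_classes(seq: str, refs: ReferenceSet, max_mm: int) -> set[str]:
    classes: set[str] = set()
    for name in refs.rrna_transcripts:
        if hamming_hits(seq, refs.sequences[name], max_mm):
            classes.add("rRNA")
            break
    for name in refs.mirna_names:
        if hamming_hits(seq, refs.sequences[name], max_mm):
            classes.add("miRNA")
            break
    return classes


def normalize_pair(
    lib_a: CollapsedLibrary,
    lib_b: CollapsedLibrary,
    exclude: set[str] | frozenset[str] = frozenset({"rRNA"}),
    refs: ReferenceSet | None = None,
    max_mm: int = 0,
    names: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Union-of-sequences table with raw counts and RPM per library.

    Sequences incident with any class in ``exclude`` (requires ``refs``) are
    dropped before normalization; each RPM column sums to 1e6 over the
    retained set.  Raises when a library is empty after exclusion.
    """
    union = sorted(set(lib_a.counts) | set(lib_b.counts))
    rows = []
    for seq in union:
        classes = _incident_classes(seq, refs, max_mm) if refs is not None else set()
        if exclude and classes & set(exclude):
            continue
        rows.append(
            {
                "sequence": seq,
                "class": ",".join(sorted(classes)) or ".",
                f"count_{names[0]}": lib_a.counts.get(seq, 0),
                f"count_{names[1]}": lib_b.counts.get(seq, 0),
            }
        )
    table = pd.DataFrame(rows)
    for name in names:
        col = f"count_{name}"
        total = table[col].sum() if not table.empty else 0
        if total == 0:
            raise ValueError(f"library {name!r} is empty after class exclusion")
        table[f"rpm_{name}"] = table[col] / total * 1e6
    table.attrs["names"] = names
    table.attrs["excluded_classes"] = sorted(exclude)
    return table


def ma_points(table: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Bland-Altman coordinates per sequence on the RPM scale.

    M = log2(a+offset) - log2(b+offset); A = mean of the two logs.
    """
    if offset <= 0:
        raise ValueError("offset must be > 0")
    a_name, b_name = table.attrs.get("names", ("a", "b"))
    la = np.log2(table[f"rpm_{a_name}"] + offset)
    lb = np.log2(table[f"rpm_{b_name}"] + offset)
    return pd.DataFrame({"sequence": table["sequence"], "A": (la + lb) / 2, "M": la - lb})


def default_threshold_grid(n_points: int = 20, low: float = 1.0, high: float = 1e4) -> np.ndarray:
    """Geometric grid of RPM thresholds, 1 to 10^4 by default."""
    return np.geomspace(low, high, n_points)


def correlation_curve(
    table: pd.DataFrame,
    thresholds: np.ndarray | list[float] | None = None,
    offset: float = 1.0,
) -> ComparisonResult:
    """PCC/SCC/KCC of the two libraries above each abundance threshold.

    At threshold t only sequences with RPM >= t in at least one library are
    retained (union rule, keeping presence/absence disagreements visible at
    low t).  PCC is computed on log2(RPM+offset); SCC (average ranks) and
    KCC (tau-b) on the RPM values.  Fewer than 3 sequences yields NaNs.
    """
    if thresholds is None:
        thresholds = default_threshold_grid()
    a_name, b_name = table.attrs.get("names", ("a", "b"))
    a = table[f"rpm_{a_name}"].to_numpy(float)
    b = table[f"rpm_{b_name}"].to_numpy(float)
    rows = []
    for t in thresholds:
        keep = (a >= t) | (b >= t)
        n = int(keep.sum())
        if n < 3:
            pcc = scc = kcc = float("nan")
        else:
            xa, xb = a[keep], b[keep]
            pcc = float(stats.pearsonr(np.log2(xa + offset), np.log2(xb + offset)).statistic)
            scc = float(stats.spearmanr(xa, xb).statistic)
            kcc = float(stats.kendalltau(xa, xb).statistic)
        rows.append({"threshold": float(t), "pcc": pcc, "scc": scc, "kcc": kcc, "n_sequences": n})
    curve = pd.DataFrame(rows)
    return ComparisonResult(ma=ma_points(table, offset), curve=curve)
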
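"""Independent brute-force oracles used by the test suite only."""

from srna_deblock._seq import reverse_complement


def brute_force_hits(query: str, reference: str, max_mm: int) -> list[tuple[int, int]]:
    """Exhaustive sliding-window Hamming scan (pure Python)."""
    out = []
    L = len(query)
    for start in range(len(reference) - L + 1):
        mm = sum(1 for a, b in zip(query, reference[start : start + L]) if a != b)
        if mm <= max_mm:
            out.append((start, mm))
    return out


def brute_force_both_strands(query: str, reference: str, max_mm: int):
    fwd = brute_force_hits(query, reference, max_mm)
    rev = brute_force_hits(reverse_complement(query), reference, max_mm)
    return fwd, rev


def average_ranks(values) -> list[float]:
    """Ranks with ties replaced by their average rank (1-based)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    rx, ry = average_ranks(x), average_ranks(y)
    n = len(x)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def kendall_tau_b(x, y) -> float:
    """Exhaustive concordant/discordant pair counting with tau-b tie correction."""
    n = len(x)
    concordant = discordant = tied_x = tied_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = (x[i] > x[j]) - (x[i] < x[j])
            dy = (y[i] > y[j]) - (y[i] < y[j])
            if dx == 0:
                tied_x += 1
            if dy == 0:
                tied_y += 1
            if dx and dy:
                if dx == dy:
                    concordant += 1
                else:
                    discordant += 1
    n0 = n * (n - 1) / 2
    return (concordant - discordant) / (((n0 - tied_x) * (n0 - tied_y)) ** 0.5)
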
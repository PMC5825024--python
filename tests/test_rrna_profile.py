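"""Presence profiles, abundant-fragment discovery, terminal enrichment."""

import numpy as np
import pytest

import srna_deblock as sd
from srna_deblock.synthetic_data import PRE_RRNA_NAME

from _oracles import brute_force_hits


def test_single_hit_additivity():
    transcript = "A" * 10 + "CGTG" + "A" * 16
    lib = sd.CollapsedLibrary(counts={"CGTG": 5})
    profile = sd.presence_profile(lib, transcript)
    assert list(np.nonzero(profile.values)[0]) == [10, 11, 12, 13]
    assert set(profile.values[10:14]) == {5}
    assert profile.total == 20


def test_overlapping_fragments_sum():
    transcript = "T" * 8 + "ACGTCGCA" + "T" * 8
    frag_a = transcript[8:14]  # covers [8,14)
    frag_b = transcript[12:18]  # covers [12,18), overlap [12,14)
    lib = sd.CollapsedLibrary(counts={frag_a: 3, frag_b: 4})
    profile = sd.presence_profile(lib, transcript)
    assert set(profile.values[12:14]) == {7}
    assert set(profile.values[8:12]) == {3}


def test_profile_equals_brute_force_accumulation():
    rng = np.random.default_rng(5)
    transcript = "".join(rng.choice(list("ACGT"), size=400))
    seqs = {}
    for _ in range(30):
        start = int(rng.integers(0, 380))
        length = int(rng.integers(15, 21))
        seqs[transcript[start : start + length]] = int(rng.integers(1, 50))
    lib = sd.CollapsedLibrary(counts=seqs)
    profile = sd.presence_profile(lib, transcript)

    expected = np.zeros(len(transcript))
    for seq, count in seqs.items():
        for start, _ in brute_force_hits(seq, transcript, 0):
            for pos in range(start, start + len(seq)):
                expected[pos] += count
    assert np.array_equal(profile.values, expected)


def test_profile_conservation_and_order_invariance():
    rng = np.random.default_rng(8)
    transcript = "".join(rng.choice(list("ACGT"), size=300))
    counts = {transcript[i : i + 20]: i + 1 for i in range(0, 200, 13)}
    lib = sd.CollapsedLibrary(counts=counts)
    profile = sd.presence_profile(lib, transcript)
    expected_total = sum(
        c * len(s) * len(brute_force_hits(s, transcript, 0)) for s, c in counts.items()
    )
    assert profile.total == expected_total
    shuffled = sd.CollapsedLibrary(counts=dict(reversed(list(counts.items()))))
    assert np.array_equal(sd.presence_profile(shuffled, transcript).values, profile.values)


def test_fragment_ranking_by_abundance():
    transcript = "".join(
        np.random.default_rng(3).choice(list("ACGT"), size=200)
    )
    a, b, c = transcript[0:25], transcript[50:75], transcript[100:125]
    lib = sd.CollapsedLibrary(counts={a: 100, b: 50, c: 10})
    peaks = sd.find_abundant_fragments(lib, transcript, top_n=2)
    assert [(p.sequence, p.rank) for p in peaks] == [(a, 1), (b, 2)]


def test_overlap_suppression_promotes_next_disjoint_fragment():
    transcript = "".join(np.random.default_rng(4).choice(list("ACGT"), size=200))
    top = transcript[20:50]  # [20,50)
    nested = transcript[22:49]  # overlaps top by 27/27 > 50% of the shorter
    disjoint = transcript[120:146]
    lib = sd.CollapsedLibrary(counts={top: 100, nested: 90, disjoint: 10})
    peaks = sd.find_abundant_fragments(lib, transcript, top_n=2)
    assert [(p.start, p.end) for p in peaks] == [(20, 50), (120, 146)]


def test_min_abundance_and_length_filters():
    transcript = "".join(np.random.default_rng(6).choice(list("ACGT"), size=200))
    short = transcript[10:25]  # 15 nt, below len_range
    rare = transcript[60:85]
    lib = sd.CollapsedLibrary(counts={short: 1000, rare: 3})
    with pytest.warns(UserWarning):
        assert sd.find_abundant_fragments(lib, transcript, top_n=3, min_abundance=5) == []


def test_planted_terminal_fragments_recovered_in_rank_order(refs):
    fractions = {"2S": 0.4, "28S_3p": 0.25, "28S_5p": 0.15, "5.8S_5p": 0.1, "miRNA": 0.1}
    config = sd.SimulationConfig(seed=13, n_reads=5000, class_fractions=fractions)
    reads, truth = sd.simulate_library(config, refs)
    lib, _ = sd.preprocess_reads([r.sequence for r in reads])
    peaks = sd.find_abundant_fragments(
        lib, refs.sequences[PRE_RRNA_NAME], top_n=4, min_abundance=10, name=PRE_RRNA_NAME
    )
    planted = sorted(truth.fragments, key=lambda f: -f.expected_count)
    assert [(p.start, p.end) for p in peaks] == [(f.start, f.end) for f in planted]
    assert [p.sequence for p in peaks] == [f.sequence for f in planted]


def test_argmax_of_2s_dominated_profile_lies_in_2s_interval(refs, preprocessed):
    lib, _ = preprocessed
    profile = sd.presence_profile(lib, refs.sequences[PRE_RRNA_NAME], name=PRE_RRNA_NAME)
    comp = refs.component("2S")
    assert comp.start <= int(np.argmax(profile.values)) < comp.end


def test_terminal_fraction_all_mass_at_5prime():
    profile = sd.PresenceProfile("t", np.concatenate([np.full(25, 7.0), np.zeros(75)]))
    f5, f3 = sd.terminal_fraction(profile, (0, 100), window=25)
    assert (f5, f3) == (1.0, 0.0)


def test_terminal_fraction_uniform_profile_is_window_over_length():
    profile = sd.PresenceProfile("t", np.full(200, 3.0))
    f5, f3 = sd.terminal_fraction(profile, (40, 140), window=20)
    assert f5 == pytest.approx(0.2)
    assert f3 == pytest.approx(0.2)


def test_terminal_fraction_zero_mass_is_nan_and_window_validated():
    profile = sd.PresenceProfile("t", np.zeros(100))
    f5, f3 = sd.terminal_fraction(profile, (0, 100), window=10)
    assert np.isnan(f5) and np.isnan(f3)
    with pytest.raises(ValueError):
        sd.terminal_fraction(profile, (0, 100), window=60)


def test_terminal_enrichment_on_planted_28s_design(refs):
    fractions = {"28S_5p": 0.45, "28S_3p": 0.45, "degradation": 0.1}
    config = sd.SimulationConfig(seed=17, n_reads=6000, class_fractions=fractions)
    reads, _ = sd.simulate_library(config, refs)
    lib, _ = sd.preprocess_reads([r.sequence for r in reads])
    profile = sd.presence_profile(lib, refs.sequences[PRE_RRNA_NAME], name=PRE_RRNA_NAME)
    comp = refs.component("28S")
    f5, f3 = sd.terminal_fraction(profile, (comp.start, comp.end), window=30)
    # terminal fragment species carry ~90% of 28S mass; degradation is diffuse
    assert f5 > 0.3 and f3 > 0.3 and f5 + f3 > 0.75
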
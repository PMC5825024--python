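"""Oligo design, off-target screening and in-silico blocking."""

import numpy as np
import pytest

import srna_deblock as sd
from srna_deblock._seq import reverse_complement
from srna_deblock.oligo_design import BlockingOligo
from srna_deblock.rrna_profile import FragmentPeak

from _oracles import brute_force_hits


def _peak(seq, start=0, transcript="t", abundance=10, rank=1):
    return FragmentPeak(seq, transcript, start, start + len(seq), abundance, rank)


def test_design_reverse_complements_the_target():
    oligos = sd.design_oligos([_peak("TGCATT")])
    assert oligos[0].oligo_sequence == "AATGCA"
    assert oligos[0].mod_5prime == "AmC6" and oligos[0].mod_3prime == "ddC"
    assert oligos[0].name == "t_0-6_block"


def test_design_involution_property():
    rng = np.random.default_rng(2)
    frags = [_peak("".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 36))))) for _ in range(10)]
    for frag, oligo in zip(frags, sd.design_oligos(frags)):
        assert reverse_complement(oligo.oligo_sequence) == frag.sequence
        assert len(oligo.oligo_sequence) == len(frag.sequence)


def test_30nt_target_yields_30nt_oligo(refs):
    two_s = refs.component_sequence("2S")
    comp = refs.component("2S")
    oligo = sd.design_oligos([_peak(two_s, comp.start, comp.transcript)])[0]
    assert len(oligo.oligo_sequence) == 30


def test_inconsistent_oligo_is_rejected():
    with pytest.raises(ValueError):
        BlockingOligo("x", "t", 0, 4, "AAAA", "AAAA")  # not the reverse complement
    with pytest.raises(ValueError):
        BlockingOligo("x", "t", 0, 4, "AACG", reverse_complement("AACG"), mod_3prime="")


def test_empty_cocktail_warns():
    with pytest.warns(UserWarning):
        assert sd.design_oligos([]) == []


def test_screen_flags_contained_mirna(refs):
    two_s = refs.component_sequence("2S")
    oligos = sd.design_oligos([_peak(two_s, transcript="pre_rRNA")])
    assert sd.screen_offtargets(oligos, refs, max_mm=0) == []

    planted = sd.design_oligos([_peak(refs.sequences["mir-003"], transcript="x")])
    warnings_found = sd.screen_offtargets(planted, refs, max_mm=0)
    assert len(warnings_found) == 1 and "mir-003" in warnings_found[0]


def test_screen_equals_brute_force_containment(refs):
    rng = np.random.default_rng(9)
    for _ in range(10):
        targets = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(4)]
        oligos = sd.design_oligos([_peak(t, transcript=f"r{i}") for i, t in enumerate(targets)])
        max_mm = int(rng.integers(0, 3))
        found = sd.screen_offtargets(oligos, refs, max_mm=max_mm)
        expected = sum(
            1
            for name in refs.mirna_names
            for t in targets
            if brute_force_hits(refs.sequences[name], t, max_mm)
        )
        assert len(found) == expected


def test_blocking_removes_contained_sequences():
    rng = np.random.default_rng(1)
    target = "".join(rng.choice(list("ACGT"), size=30))
    other = "".join(rng.choice(list("ACGT"), size=22))
    sub = target[4:26]  # 22 nt exact subfragment of the target
    oligo = sd.design_oligos([_peak(target)])
    lib = sd.CollapsedLibrary(counts={target: 80, sub: 15, other: 20})
    blocked, report = sd.simulate_blocking(lib, oligo, max_mm=0)
    assert blocked.counts == {other: 20}
    assert report.blocked_per_oligo["t_0-30_block"] == 95
    assert report.r_before == 115 and report.r_after == 20


def test_blocking_mismatch_threshold_boundary():
    rng = np.random.default_rng(7)
    target = "".join(rng.choice(list("ACGT"), size=30))
    two_subs = list(target)
    for i in (3, 11):
        two_subs[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[two_subs[i]]
    three_subs = list(two_subs)
    three_subs[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[three_subs[20]]
    lib = sd.CollapsedLibrary(counts={"".join(two_subs): 5, "".join(three_subs): 5})
    blocked, _ = sd.simulate_blocking(lib, sd.design_oligos([_peak(target)]), max_mm=2)
    assert blocked.counts == {"".join(three_subs): 5}  # 3 substitutions: retained


def test_blocking_never_increases_counts_and_preserves_untargeted(refs, preprocessed):
    lib, _ = preprocessed
    two_s = refs.component_sequence("2S")
    comp = refs.component("2S")
    oligos = sd.design_oligos([_peak(two_s, comp.start, comp.transcript)])
    blocked, _ = sd.simulate_blocking(lib, oligos, max_mm=2)
    for seq, count in blocked.counts.items():
        assert count == lib.counts[seq]
    assert blocked.R < lib.R
    assert two_s not in blocked.counts


def test_untargeted_class_proportions_are_non_decreasing(refs, preprocessed):
    lib, _ = preprocessed
    comp = refs.component("2S")
    oligos = sd.design_oligos([_peak(refs.component_sequence("2S"), comp.start, comp.transcript)])
    blocked, report = sd.simulate_blocking(lib, oligos, max_mm=2, refs=refs)
    # classes disjoint from the target gain proportion after renormalization
    assert report.composition_after["miRNA"] >= report.composition_before["miRNA"]
    assert report.composition_after["5S"] >= report.composition_before["5S"]
    assert report.residual_fraction["2S"] < report.composition_before["2S"]


def test_design_then_block_removes_all_targeted_reads(refs, simulated, preprocessed):
    """Zero-error planted species vanish entirely after design -> block."""
    _, _, truth = simulated
    lib, _ = preprocessed
    from srna_deblock.synthetic_data import PRE_RRNA_NAME

    peaks = sd.find_abundant_fragments(
        lib, refs.sequences[PRE_RRNA_NAME], top_n=1, min_abundance=10, name=PRE_RRNA_NAME
    )
    blocked, report = sd.simulate_blocking(lib, sd.design_oligos(peaks), max_mm=2)
    targeted = {f.sequence for f in truth.fragments if f.label == "2S"}
    assert targeted and all(seq not in blocked.counts for seq in targeted)


def test_blocked_profile_is_near_zero_inside_targeted_interval(refs, preprocessed):
    import numpy as np

    from srna_deblock.synthetic_data import PRE_RRNA_NAME

    lib, _ = preprocessed
    transcript = refs.sequences[PRE_RRNA_NAME]
    comp = refs.component("2S")
    oligos = sd.design_oligos([_peak(refs.component_sequence("2S"), comp.start, comp.transcript)])
    blocked, _ = sd.simulate_blocking(lib, oligos, max_mm=2)
    before = sd.presence_profile(lib, transcript).values[comp.start : comp.end]
    after = sd.presence_profile(blocked, transcript).values[comp.start : comp.end]
    assert after.max() <= 0.01 * before.max()
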
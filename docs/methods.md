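# Methods

## Scope and model

The package treats rRNA contamination of small-RNA libraries as a
sequence-level phenomenon: a small set of discrete, highly abundant rRNA
fragments (the intact 30 nt 2S rRNA; 5'/3' terminal fragments of 5.8S and
28S; a 3' fragment of 5S) superimposed on a diffuse degradation background,
alongside the miRNA population of interest. Everything downstream — QC,
annotation accounting, profile-based fragment discovery, oligo design,
in-silico blocking, concordance analysis — operates on exact nucleotide
sequences and bounded-mismatch full-length alignment; no probabilistic
binding or thermodynamic model is used.

## Preprocessing

Reads containing any non-ACGT character are discarded. The 3' adapter is
located by a perfect match of its first 7 nt (`TGGAATT`); the *leftmost*
occurrence wins (shortest-insert convention), and reads without the seed
are discarded rather than kept untrimmed, since an untrimmed read would
inject adapter sequence into the library. HD signatures (default 4 nt) are
then stripped from both ends, and inserts outside the valid range (default
18–36 nt, bracketing 21–23 nt miRNAs and the 30 nt 2S with margin) are
dropped. Valid inserts are collapsed exactly; complexity is defined as
NR/R, the number of distinct sequences over the redundant total — the form
consistent with the published accounting tables this layout mirrors.

## Matching

A query *hits* a reference at position p when the Hamming distance between
the full query and the same-length reference window is at most `max_mm`
(0–2); no gaps, no partial alignments. The implementation views the
reference as a byte array and compares all windows at once with numpy; at
the scales this package targets (references of a few kb, thousands of
distinct queries) this is faster in practice than maintaining a seed index
and trivially correct. The test suite verifies it against an independent
pure-Python exhaustive scan on hundreds of random instances.

Strand policy: both strands for the genome surrogate; sense only for
transcript references (rRNA, miRNA), which avoids double-counting antisense
artefacts in annotation proportions. Class incidence is per-class
presence/absence — one sequence may count toward genome, rRNA and miRNA
simultaneously, and abundances are not split across loci. Component
attribution (18S/5.8S/2S/28S) requires ≥ 1 nt overlap between a sense hit
on the pre-rRNA and the component interval; hits entirely within
transcribed spacers count toward the rRNA total only. Annotation defaults
to 0 mismatches, with 1 and 2 available.

## Presence profiles and fragment discovery

The presence profile of a transcript adds, at every covered position, the
redundant count of each library sequence with a perfect hit there. Every
perfect hit contributes (all-hits policy), so the profile total always
equals Σ(count × length × number-of-hits) — a conservation law the tests
assert. Fragment discovery ranks distinct perfectly matching sequences of
oligo-designable length (default 20–35 nt) by redundant abundance,
suppresses candidates whose interval overlaps a higher-ranked one by more
than 50% of the shorter interval (preventing near-duplicate oligos against
one peak), and returns the top N. Ties are broken by position, then
sequence, making the ranking deterministic. Terminal enrichment of a
component is the fraction of its profile mass within a window of each end.

## Oligo design and in-silico blocking

Each selected fragment yields one oligo: the DNA reverse complement of the
target, annotated with 5' amino-C6 and 3' dideoxy-C modifications and named
`<transcript>_<start>-<end>_block`. Hybridization is proxied by
*containment*: a library sequence is blocked when its full length aligns
within some oligo's target sequence at ≤ 2 mismatches (configurable). This
proxy is what explains the disappearance of shorter 2S subfragments when
the full-length 2S is blocked, and it keeps the operation a pure set
filter: counts of surviving sequences are never altered, so untargeted
populations keep their exact abundances and ranks. The off-target screen
applies the same containment rule to the mature miRNA catalogue and warns
about any miRNA an oligo would co-block. No melting-temperature or
secondary-structure screening is attempted.

## Concordance

Libraries are compared on reads-per-million of the retained denominator set
(default: everything not rRNA-incident), computed after excluding the
contaminant class so that sequencing-depth differences between blocked and
non-blocked libraries cancel. MA coordinates use a 1 RPM pseudo-count.
Correlation curves restrict, at each threshold t (geometric grid, 1–10⁴
RPM), to sequences at ≥ t RPM in *at least one* library — the union rule
keeps presence/absence disagreements visible at low abundance, where most
variability between libraries lives. Pearson is computed on log2(RPM+1);
Spearman uses average ranks and Kendall the tau-b tie correction, both on
the RPM scale, because zero-inflation makes ties common. Fewer than 3
retained sequences yields missing values rather than a coefficient.

## Synthetic data

The generator is the package's study design, not a convenience fixture.
References are scaled down — 18S 200 nt, 5.8S 123 nt, 28S 400 nt, spacers
50 nt, 5S 120 nt, 50 mature miRNAs of 23 nt — because real rRNA lengths add
nothing to the logic being exercised; the 2S is kept at its true 30 nt
because the size-selection story depends on it. The pre-rRNA carries the
ETS–18S–ITS1–5.8S–ITS2a–2S–ITS2b–28S layout; all transcripts plus random
background form a genome surrogate. Default read composition emulates a
heavily contaminated reproductive-tissue library: 82% 2S, 1.1% each of
five terminal-fragment species (placed flush to component ends, mirroring
the observed 5'/3' enrichment), 4% uniform-position degradation, 7.5%
miRNA, 1% unannotated background. miRNA abundances are log-normal
(σ = 1.5, long-tailed); read lengths are 21/22/23 nt with probabilities
0.2/0.6/0.2, taken as 3' truncations of the mature sequence, giving the
characteristic 22 nt modal size class. Reads are `4 random nt + insert +
4 random nt + adapter` truncated to 50 nt, with constant high quality
(the analysis never uses qualities beyond N-filtering) and optional
uniform per-base substitution error applied last.

Two generator properties matter for interpretation. First, reference
sequences are screened for the adapter seed and HD signatures are resampled
when they would create a spurious seed match upstream of the true adapter,
so error-free reads trim back to their exact insert; real libraries have a
small irreducible mis-trim rate (~4⁻⁷ per position) that this design
removes by construction. Second, all randomness flows from a single
recorded seed, making every simulated dataset byte-reproducible. The
generator does not model ligation bias of standard adapters, indels,
quality decay, or piRNA populations — so passing tests demonstrate the
pipeline's correctness on the stated population structure, not robustness
to those real-data features.

## Numerical and scale choices

Problem sizes in the tests are chosen for statistical resolution at
interactive runtimes: 4,000–20,000 reads for distributional checks
(multinomial 3σ bands at these n are a few tenths of a percent) and a
single 200,000-read run for the end-to-end blocking bound. Stochastic
assertions use fixed seeds and 3σ tolerances; exact assertions (round-trip
recovery, conservation laws, determinism) use equality. Degenerate inputs
are defined rather than accidental: empty libraries make complexity an
error, zero-mass components make terminal fractions missing, empty
fragment lists design an empty cocktail with a warning.

## Known limitations

Containment with a global mismatch budget is a coarse hybridization proxy:
it ignores position-dependent binding energetics and cannot block reads
that straddle a target boundary (visible in the worked example as residual
"2S-annotated" degradation reads overlapping the 2S interval by a few nt).
Annotation proportions depend on the mismatch setting, and the synthetic
genome surrogate lacks repeats, so multi-mapping behaviour is milder than
in a real genome. The comparison module quantifies concordance only; it
deliberately performs no differential-expression testing.
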
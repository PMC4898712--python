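# Methods

This note records the models, parameter choices and numerical conventions
behind `rrnatax`, and what the synthetic benchmarks do and do not
demonstrate.

## Classification model

Reads are scored against full-length SSU rRNA references by the fraction
of the read's distinct k-mers found in the reference,
`S(q, r) = |W_k(q) ∩ W_k(r)| / |W_k(q)|`. The score is deliberately
asymmetric: fragments of 60–400 nt are scored against ~1.5 kb references,
and normalising by the query's words makes an exact substring score 1.0
regardless of reference length. Jaccard similarity would penalise short
fragments for everything they do not cover. Both strands are always
evaluated (random-primed reverse transcription with second-strand
synthesis yields reads from either strand); the better strand wins per
reference. K-mers containing non-ACGT characters contribute nothing.

**Word length k = 8** (default). On random sequence an 8-mer has a
4⁻⁸ ≈ 1.5 × 10⁻⁵ per-position collision rate, so unrelated ~1.5 kb
references share only a handful of words, while a 60 nt fragment still
carries 53 words — enough resolution for a fractional score. Shorter k
loses discrimination between related genera; longer k makes short or
error-laden fragments word-poor.

**Taxonomy projection.** Hits within `top_window = 0.02` of the best
similarity vote, and the read receives the lowest common ancestor of the
voters' lineages over the fixed six-rank ladder (domain → genus). The
window reflects that fragment scores are coarse-grained: a 100-word
fragment quantises similarity in steps of 0.01, so near-ties are real
ties. Reads whose best score is below `min_similarity = 0.40` are
reported as *unclassified* rather than dropped — for direct rRNA
sequencing the unclassified fraction is a finding, not noise. Genus is
the deepest rank carried because short fragments rarely support
species-level claims.

**Abundance.** Assignment weights are dereplication counts, so tables
report read density: the percentage of original (not unique) reads per
taxon. Domain tables normalise over everything classified; deeper ranks
normalise within each domain, giving the two-level presentation
(domain densities, then per-domain phylum densities) typical of
three-domain rRNA surveys. Assignments shallower than the requested rank
pool under `unclassified <parent>` so each group still sums to 100 %.

## Cleaning

Quality salvage keeps every maximal run of bases with Phred ≥
`min_quality = 20` that is at least `min_length = 50` nt long. Maximal
runs (rather than sliding-window averages) are the simplest scheme that
never lets a below-threshold base into downstream analysis while keeping
the good parts of a partially poor read; one read may yield several
sub-reads. Reads without quality strings pass through whole, marked by a
null quality field. `N` bases are retained through trimming (they encode
base-caller ambiguity, not low quality) but any fragment with more than
10 % `N` is dropped, since its word content is unusable. Dereplication is
exact forward-strand string identity; strand canonicalisation is left to
the search stage so dereplication is order-independent.

## Pairwise alignment

`align_pair` is a banded semi-global Gotoh alignment: the query must be
aligned end to end, the reference contributes a free-overhang local
segment (fragments land anywhere inside near-full-length references).
Scoring is match +1, mismatch −1, gap open −2, gap extend −1, with the
convention that the *first* base of a gap costs the open penalty (a gap
of length L costs 2 + (L − 1)). The band (half-width 32) is centred on
the diagonal carrying the most shared 8-mers; ties go to the smallest
offset, and a pair sharing no words falls back to an unbanded sweep.
Traceback is three-state (match/insert/delete layers with their own
pointers) so gap runs are reconstructed exactly — this matters because
the primer audit counts events per alignment column. End-column ties at
the last row resolve to the leftmost reference position.

## Chimera detection

A read is chimeric when some breakpoint *b* admits a two-parent
explanation better than any single reference:
`score = max_b min(S(q[:b]), S(q[b:])) − S_full ≥ min_improvement`, with
distinct best prefix/suffix parents. Breakpoints are scanned at
word-length steps with `min_segment = 60` nt on each side (a segment
much shorter than that carries too few words to attribute reliably);
`min_improvement = 0.10` keeps the detector away from the score jitter
of related references. Exact substrings of an indexed reference can
never be flagged (`S_full = 1` is unbeatable), which pins the false-
positive rate on pure reads at zero by construction. Shared words
between similar parents flatten the score curve around the true
junction, so the reported breakpoint is the midpoint of the maximal-
score plateau. Both orientations are scanned and the better one kept,
making verdicts invariant to reverse complementation. The chimera stage
runs only in the amplicon pipeline: fragments of directly sequenced rRNA
never passed through PCR, so flagging them would only discard real
divergent molecules.

## Primer-site audit

Primer windows are located on *references*, not raw reads: the read is
aligned to its best-matching reference and events are read off alignment
columns, which is robust to fragments that cover a site only partially
(those are reported `site_covered = false` and contribute no counts).
Window location is an IUPAC-aware Hamming scan (a primer ambiguity code
matching the template base counts as a match); reverse primers are
matched as their reverse complement. The location cap defaults to
`max_mismatches = 5` — generous, because heavily mismatched sites are
exactly the ones worth finding. Insertions sit between reference
positions and are attributed to a window only when both flanking
positions are inside it. The per-taxon summary emits *both* ratio
orientations — reads-with-site / total events, and total events /
reads-with-events — because both conventions are in circulation and they
are not reciprocals of the same pair of quantities; columns are named
explicitly so neither is mistaken for the other.

## PCR / qPCR simulator

Amplification is `copies_i(n) = copies_i(0) · (1 + e_i)^n` with a
constant per-cycle efficiency `e_i ∈ [0, 1]`; the stochastic mode
replaces the closed form with per-cycle Binomial(molecules, e) draws,
which reproduces the closed form in expectation and adds the dispersion
that matters at low template numbers. No plateau/saturation term is
modelled: bias ratios are interpreted at fixed cycle counts, and a
carrying-capacity parameter would be unconstrained by anything the
simulator is compared against. Differential efficiencies make the
post-PCR ratio of two equal inputs grow as `((1+e_A)/(1+e_B))^n` — the
mechanism by which templates become over- or under-represented.

Standard curves are ordinary least squares of Ct on log₁₀(copies)
(slope b < 0 required; efficiency `(10^(−1/b) − 1) · 100 %`, so the
textbook slope −3.3219 gives 100 %). Quantification inverts the curve;
at zero noise `quantify(ct_from_copies(x)) = x` to floating-point
precision across 10³–10⁸ copies. Mixture ratios are expressed relative
to the smallest component. Replicate structure (3 × 3) and six-point
ten-fold dilution series are configuration defaults.

## Synthetic data

The generator emulates random-primed RT fragmentation: references are a
common random root mutated independently per taxon to a target
divergence (default 10 %); fragments draw a reference by proportion, a
length from a configurable distribution (default uniform 60–400 nt), a
start uniform over the positions where the fragment fits, and a strand
(reverse-complemented with probability 0.5). Drawing the start over the
positions where the fragment fits — rather than clipping overhanging
fragments at the reference end — keeps the realised length distribution
exactly the configured one. Errors are layered on separately: per-base
substitutions and indels at configured rates, Gaussian-ish Phred
qualities around a mean of 30, and occasional injected low-quality
stretches to exercise quality salvage. A 13-phylum preset (five dominant
phyla carrying ~92.5 % of the bacterial signal plus eight minor groups)
supports end-to-end demos.

Not emulated: platform-specific homopolymer errors, priming-site
sequence bias, rRNA secondary-structure coverage bias, and chimera
formation (chimeras are constructed explicitly in tests). Passing the
synthetic benchmarks therefore shows the pipeline recovers composition
under the stated error model, not that it is robust to every artefact of
real sequencers; the fragment-length default is a declared choice, not
an inference about any particular instrument.

## Benchmarks computed by the test suite

The acceptance tests and `scripts/acceptance.py` compute, at run time:
density tables from fixed tabulated counts (domain densities
99.53/0.01/0.46 and the 92.5 % dominant-phyla sum follow by arithmetic
from those counts); the 1:3:8:2:10 five-clone mixture ratio; exact
recovery of a noise-free standard curve with R² = 1 and ≈100 %
efficiency; oracle equivalence of the word score (brute-force set
enumeration) and the banded aligner (full-matrix DP) on random pairs;
genus-level composition recovery within 3σ binomial on 20 000 error-free
fragments at 10 % divergence, and within 5 percentage points at a 1 %
substitution rate; zero chimera false positives on pure substrings with
≥95 % sensitivity on constructed 50/50 chimeras of ≤90 %-identical
parents; and exact (6,0,0)/(2,0,0) event counts for fragments of a
template engineered with six forward-site and two reverse-site
substitutions. Problem sizes (20 000 fragments for test recovery, 10 000
in the acceptance script; 1 000/500 pure reads; 200 chimeras; 200
stochastic replicates) were chosen to make the binomial bounds sharp
while keeping a full run under a minute.

## Known limitations

* The word score saturates: two references more similar to each other
  than one word-survival length cannot be distinguished by very short
  fragments, and the LCA then shallows the call (by design).
* Dereplication is exact-match only; near-duplicate collapsing (e.g.
  single-error reads) is left to the similarity stage.
* Chimera detection assumes both parents are indexed; novel-parent
  chimeras score as unclassified, not chimeric. Three-parent chimeras
  are out of scope.
* The banded aligner is exact only while the optimal path stays within
  the band of the seeded diagonal; pairs related through large
  rearrangements should be aligned unbanded.
* Amplification efficiencies are free inputs; the simulator demonstrates
  the bias mechanism but does not infer efficiencies from sequence.
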
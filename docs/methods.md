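# Methods

This note documents the models, parameter choices and numerical decisions
behind `cryptokin`, and what the simulation-based validation does and does
not establish.

## Segment-set encoding

A phased diploid genome is represented against a reference as two binary
strings of length M (1 = single-base difference at that position; indels
and multi-base variants are excluded).  Chromosomes are laid end to end in
reference FASTA order, giving one genome-wide 0-based coordinate axis.
Each string is cut into ⌈M/L⌉ non-overlapping segments of L = 30 000 bp
(trailing partial segments are right-padded with reference-matching
zeros so all individuals share one segment grid).  Segment j of a
haplotype becomes the integer

    element = int(segment bits, MSB first) + j*L

computed with arbitrary-precision arithmetic — the sum, not the
concatenation, of segment data and segment position.  Summation admits, in
principle, collisions between different (data, position) pairs; for
sparse variant patterns the data term is either 0 or astronomically larger
than any position term, so cross-segment collisions require ~L-fold
coincidences and are ignored rather than redesigned away.  Within one
segment index, element equality is exactly equality of variant patterns,
which is the property the score relies on.

A diploid genome yields 2 elements per segment (one per haplotype), 2s in
total (s = 100 000 for a human genome).  Where strict set semantics are
needed (the cryptographic layer), a homozygous-identical segment's second
copy is shifted by 2^(L+1), far outside the value range of any single
element, so two homozygous-identical individuals still collide on both
copies while each individual's set stays duplicate-free.

## Matched-segment relatedness score

For a pair of individuals, segment j contributes the multiset-intersection
size of their two-element segment multisets: 0, 1 or 2 shared haplotypes,
cross-haplotype matches included.  The genome-wide sum `total_matched`
∈ [0, 2s] is the relatedness statistic; related ⟺ `total_matched` ≥ t.
The equivalent distance form is 2s − `total_matched`.  The boundary value
t itself classifies as related (an arbitrary but fixed tie-break).

Threshold calibration from labeled pairs uses the floor midpoint of the
separating gap when the classes separate, otherwise an exhaustive scan
minimizing training misclassifications with ties broken toward the lower
threshold.  The rule is deliberately simple and pluggable; the validation
study instead operates at the **zero-false-positive point** — one more
than the highest unrelated score — because the headline claim is about
separation, not about a particular calibration procedure.

## Privacy layer

*Private key.*  Every element s is hashed to h_24(s + r): SHA-256 of the
canonical big-endian encoding of the arithmetic sum, truncated to the
first m = 24 bits.  The salt r is a public, 100-bit, per-protocol-instance
constant shared by all participants — identical segments must hash
identically across individuals, so the salt's role is to invalidate
precomputed dictionaries, not to separate users.  A hash output of 0 is
remapped to 1 (deterministically, hence consistently across parties)
because the zero field element is invisible to power-sum syndromes.

*Public key.*  The default backend is the syndrome (PinSketch-style)
secure sketch for set difference over GF(2^24): publish the d odd power
sums syn_i = Σ_a a^(2i−1) (i = 1…d) of the hashed set, d = 2(k − t), plus
a SHA-256 verification hash of the sorted element set.  Two size-k sets
share ≥ t elements exactly when their symmetric difference is ≤ d.
Recovery XORs published and own syndromes (shared elements cancel), fills
even syndromes by squaring (S_2j = S_j² in characteristic 2), runs
Berlekamp–Massey to get the difference locator, finds its roots, and
accepts only if the reconstructed set matches the verification hash.
Failures carry no payload derived from the other party's data.

An alternative backend publishes the top d coefficients of the monic
characteristic polynomial Π(x − a) (the Juels–Sudan form).  Newton's
identities convert those coefficients to power sums p_1…p_d, after which
the same decoder applies — but only d consecutive syndromes are available,
so unique decoding reaches ⌊d/2⌋ differences.  Restoring the full radius
requires list decoding, which is out of scope; the syndrome backend is the
default precisely because it meets the full |A△B| ≤ d contract with the
same d·m-bit publication size.

*Field arithmetic.*  GF(2^m) uses the lexicographically-first primitive
polynomial of degree m (computed, then cached; 0x100001B for m = 24),
log/antilog tables (~200 MB at m = 24, built once per process), and
vectorized polynomial kernels.  Root finding evaluates the locator at the
decoder's own elements first (those roots are free), then factors the
remaining polynomial by Berlekamp-trace splitting with lazily reduced
random trace candidates; degree-2 factors are solved in closed form via a
precomputed Artin–Schreier solution basis.  A candidate that fails to
split a factor provably fails for all its sub-factors, so recursion
resumes at the next candidate index.  For m ≤ 16 the whole field is small
enough to evaluate directly.

*Leakage accounting.*  The sketch reveals at most d·m bits.
`security_margin(assumed_entropy, params)` reports the residual and flags
the instance as relatively secure only when the residual strictly exceeds
100 bits.  Genome entropy is an input parameter: estimating it is a
population-genetics question outside this package, and at the validation
scale (k = 4 000, t ≈ 270, d ≈ 7 460) the leakage bound exceeds any
plausible 60 Mb genome entropy — the scaled study validates correctness
and correspondence, not the entropy margin, which only the full 3 Gb
setting can supply.

*Hash-collision margin.*  With 24-bit hashes, an individual's k ≈ 4 000
elements collide internally with probability ~k²/2^25 ≈ 0.5 per genome;
`publish` drops to one copy per value (duplicate elements would otherwise
cancel in characteristic 2), and unrelated pairs gain ~k²/2^24 ≈ 1
spurious shared element.  The decision boundary is therefore fuzzy by a
few elements; the end-to-end agreement check excludes pairs within a
margin (max(6, 3k²/2^24) score units) of the threshold.  At human scale
(k = 200 000) the spurious overlap grows to ~2 400 elements — still small
against a cut-off of 25 390 matched segments.

## Build-independent encoding

Segments anchor at known common SNPs: greedy left-to-right, each anchor at
or beyond the previous window's end opens a new [anchor, anchor+L) window,
so windows never overlap and all parties derive the same grid from the
same anchor list.  Each variant in a window contributes its flanking
sequence — 500 bp each side, 1000 bp total, the variant base itself
excluded, upper-cased, N-padded at contig edges.  Flank signatures are
concatenated in ascending position per haplotype and hashed with the same
salted hash, so downstream sketching is unchanged.  Windows with no
variants emit a reserved element derived from the anchor id, keeping
element counts comparable.  Anchors are treated as reference landmarks;
the anchor SNP need not be a variant of the individual.  The Hg18/Hg19
comparison requires external downloads, so build portability is exercised
on synthetic build pairs: the acceptance script measures the flank-hash
mismatch fraction on two generated builds differing in 1 of 500 SNP
flanks (0.002 by construction, the operation verified rather than the
rate re-estimated).

## Pedigree simulator

*Founders.*  Default is a neutral coalescent (msprime: N_e = 10 000,
μ = 1.25×10⁻⁸/bp, within-founder recombination 10⁻⁸/bp), which supplies
both a realistic site-frequency spectrum (mostly rare variants) and
linkage disequilibrium.  LD matters: with independent sites, every 30 kb
common-variant haplotype would be essentially unique and a
common-variant-only encoding would spuriously separate all degrees; with
coalescent LD, common 30 kb haplotypes recur across unrelated individuals
and the common-only baseline degrades exactly as it should.  A parametric
i.i.d.-per-site model (configurable common/rare densities and frequency
ranges) remains available for analytically transparent unit tests.

*Transmission.*  Each child haplotype is a mosaic of one parent's two
haplotypes with breakpoints drawn as a Poisson process at 10⁻⁷ per bp per
meiosis, independent across meioses; no de-novo mutation.  Haplotypes are
sorted site-index arrays, so a 60 Mb genome with ~160 k segregating sites
simulates thousands of meioses per minute.

*Mating and labels.*  Mating is non-polygamous; eligibility requires no
shared ancestor within `mating_unrelated_depth` (default 2) generations,
relaxed stepwise only when no pairing exists.  Fully-outbred mating ("no
shared ancestor at all") is impossible beyond log2(n_founders)
generations — ancestor sets double every generation — so no small founder
pool can honor it for 10 generations; this is why a depth-limited rule is
the default.  Relationship labels are always computed from the ancestry
graph: degree-g cousins share a most recent ancestral couple exactly g+1
generations above both.

*Why island fission.*  Under plain random mating from 60 founders,
essentially no pair has its closest shared couple 6–7 generations back
(coalescence happens much sooner), and a pair sharing *only* one couple
that far back shares E ≈ 2(mG+c)/2^(m−1) ≈ 0.07 IBD blocks on a 6-Morgan
genome — undetectable for >90% of such pairs by any method.  The default
`fission` scheme therefore splits the founders into two never-mixing
islands (their cross pairs are unrelated at every generation) and
recursively splits each island's population at scheduled generations
(defaults: generations 4–9), dividing every sibship across the two halves
of a split.  Pairs from subpopulations separated g+1 generations ago then
share many ancestral couples at exactly depth g+1 and nothing closer:
clean degree-g labels, with enough accumulated shared ancestry (tens of
expected IBD blocks at degree 5) for detection to be a fair test.  This
mirrors how distant-cousin separation arises in any deep pedigree bred
from a small founder pool, where distant cousins inevitably share many
distinct ancestral paths rather than a single couple.  Population sizes
keep each subpopulation at ~12 members (couples have at most 4 children),
growing from 60 founders to ~1 500 individuals in the last generation.

*Errors.*  Sequencing errors flip variant↔reference calls independently
per polymorphic site per haplotype (default 0.002); phasing errors follow
the switch-error model — at each heterozygous site the maternal/paternal
orientation toggles with the switch probability (default 0.005) and
persists until the next switch, preserving unphased genotypes.  The
calibration loop bisects a single scale factor on (sequencing, switch)
rate caps until simulated sibling and unrelated mean matched-segment
counts hit user-supplied targets; with no real data in scope, the
validation study runs at the default rates and the loop is exercised
against simulation-derived targets.

## The scaled validation study

Conditions: 60 Mb genome (2 000 segments), 60 founders, 10 generations,
recombination 10⁻⁷/bp, default error rates, 50 pairs per cousin degree
1–6 plus 50 sibling pairs and 500 unrelated pairs, three seeds.  Scoring
uses interned per-segment keys — within a segment index, element equality
is pattern equality, so interning (segment, variant pattern) pairs gives
bit-identical scores to element comparison (asserted against
`similarity()` in the unit suite) without constructing 30 000-bit
integers for a thousand individuals.

Observed (seed 1): mean `total_matched` falls monotonically from ~1 540
(siblings) through ~900/740/610/520/440/340 (degrees 1–6) to ~170
(unrelated, maximum 269).  At the zero-false-positive threshold (270),
degree-5 sensitivity is 96–100% across seeds while degree 6 drops to
~88% — the maximum cleanly separable degree is five.  The
common-variant-only baseline (MAF ≥ 0.05) separates strictly fewer
degrees under identical error realizations.  The secure layer, run at
t = the same threshold with d = 2(k − t), reproduces the plaintext
classification on every evaluated pair away from the hash-collision
margin, and the GF(2^8) oracle confirms exact decoding against brute
force over ≥ 1 000 random instances.

What this does and does not show: the simulator emulates founder
diversity, recombination, pedigree structure and call errors, but not
population stratification within islands, genotype-calling artifacts
correlated along the genome, reference bias, or real phasing-tool error
patterns; and the 60 Mb scale compresses the genome ~50-fold, so absolute
thresholds (270 of 4 000 here) do not transfer to the 3 Gb setting
(cut-off 25 390 of 200 000) — only the qualitative separation result and
the exactness of the cryptographic layer do.

## Numerical and engineering choices

- Segment grids, coordinates and serialized artifacts are deterministic;
  every randomized path takes an explicit seed, and identical
  configurations reproduce bit-identical pedigrees and sketches.
- Genomic-set files are a JSON header plus sorted decimal big integers,
  one per line; sketch files are a JSON header plus base64-packed field
  elements, d·m bits exactly, byte-stable across platforms.
- Berlekamp–Massey runs on 2d syndromes (the even ones reconstructed by
  squaring), guaranteeing unique decoding up to d differences; decoding
  failure is detected by locator degree, a splitting-field check
  (x^(2^m) ≡ x mod σ), root count, syndrome recomputation and finally the
  verification hash, in increasing order of cost.
- Degenerate inputs fail loudly: empty sets cannot be published,
  duplicate field elements are rejected unless the caller opts into
  collision dropping, unphased VCF genotypes raise an error naming the
  record, and out-of-range variant positions name the offender.

## Known limitations

- The decoding radius of the characteristic-polynomial backend is half
  that of the syndrome backend (no list decoding).
- Relatedness threshold selection is a simple training-set rule; no
  principled cut-off derivation (e.g. from a mixture model of score
  distributions) is provided.
- The simulator's "unrelated" pairs share no pedigree ancestor but do
  share coalescent ancestry, as real "unrelated" humans do; at 60 Mb this
  produces a nonzero identical-by-state background (~170 of 4 000
  segment slots) that any threshold must clear.
- Arithmetic (rather than positional) combination of segment data and
  position is kept for fidelity to the encoding definition despite its
  theoretical collision possibility, as documented above.
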
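# cryptokin

Privacy-preserving detection of genetic relatives from phased genomes.

Direct-to-consumer relative finding normally requires everyone to upload
their genotypes to one database, where all pairs are compared.  `cryptokin`
implements a protocol in which two individuals can learn **whether they are
related — and nothing else — by exchanging only public keys**, with no
trusted third party.  Because the encoding uses *all* single-base variants
(rare ones included) rather than a fixed panel of common SNPs, it separates
far more distant relatives than common-variant approaches: on simulated
pedigrees the tool cleanly detects fifth-degree cousins.

It is aimed at statistical-genetics and genomic-privacy researchers who
want a working, testable implementation of set-based relatedness scoring, a
syndrome secure sketch over GF(2^24), and the pedigree simulator used to
validate them.

## The method in brief

**Encoding.**  Each phased haplotype is compared to the reference genome
and reduced to a binary string (1 = single-base difference).  The string is
cut into non-overlapping segments of L = 30 000 bp; segment *j* of
haplotype *H<sub>ij</sub>* becomes one big-integer set element

&nbsp;&nbsp;&nbsp;&nbsp;*s<sub>ij</sub>* = int(*H<sub>ij</sub>*) + *j*·L,

the arithmetic sum of the segment's bit pattern and its genome-wide start
coordinate.  A diploid genome of M bp yields a set S<sub>i</sub> of
2·⌈M/L⌉ elements (2·100 000 for a human genome).

**Relatedness score.**  For two individuals, each segment contributes 0, 1
or 2 — the number of haplotype pairs with identical variant content there
(cross-haplotype matches count).  The genome-wide sum `total_matched`
estimates relatedness; a pair is *related* when it reaches a threshold *t*
calibrated on labeled training pairs.

**Privacy layer.**  Each element is replaced by the first 24 bits of
SHA-256(*s<sub>ij</sub>* + *r*), with *r* a public 100-bit salt shared by
the protocol instance; the hashed set is the private key.  The public key
is a secure sketch for set difference: interpreting the 24-bit elements as
members of GF(2^24), it publishes the *d* odd power sums
Σ<sub>a</sub> a^(2i−1), i = 1…d, with tolerance d = 2(k − t), plus a
verification hash.  Anyone holding a private set within symmetric
difference *d* of the published one can decode exactly that difference
(Berlekamp–Massey + root finding) and confirm it against the hash; anyone
else learns only that decoding failed.  The sketch reveals at most d·m
bits, which `security_margin` compares against a genome-entropy estimate
(the protocol is considered comfortable only when >100 bits remain).

**Build independence.**  When parties use different reference builds,
coordinates disagree.  The alternative encoding anchors segments at known
common SNPs and represents each variant by its 500 bp flanking sequence on
both sides (1000 bp, variant base excluded), concatenated per segment and
hashed — identical local sequence gives identical elements in any build.

**Validation data.**  A pedigree simulator produces founders from a neutral
coalescent (realistic site-frequency spectrum *and* linkage
disequilibrium), then non-polygamous random mating with recombination
(10⁻⁷ per bp per meiosis), labeled cousin pairs of degree 1–6 via an
island-fission design, and sequencing/phasing-switch error injection with
a calibration loop.

## Worked example

Simulate a one-generation pedigree (8 founders, 400 kb genome), encode it,
and score all pairs:

```bash
cryptokin simulate --seed 5 --genome-length 400000 --founders 8 \
    --generations 1 --scheme random --out-dir sim
printf '1\t400000\t0\t60\t61\n' > sim.fai
cryptokin encode sim/pedigree.vcf --fai sim.fai --segment-length 10000 --out-dir sets
cryptokin score sets/*.set --out scores.tsv
```

`scores.tsv` holds `total_matched` out of 2×40 = 80 segment slots per
pair.  Child `G1I0` (parents `F4` and `F2`, per `sim/pedigree.tsv`) scores
48 against its parent `F2` — on every segment one of the child's
haplotypes is a recombinant copy of a parental one, minus segments broken
by recombination or matched twice — while unrelated founder pairs score
around 17–24 (segments empty of variants on both sides match by chance).

Run the secure protocol at threshold t = 48 (so d = 2(80−48) = 64):

```bash
cryptokin make-params --k 80 --t 48 --m 24 --seed 1 --out params.json
cryptokin sketch sets/G1I0.set --params params.json --out child.priv
cryptokin publish child.priv --params params.json --out child.pub
# published d=64 backend=syndrome; leakage <= 1536 bits

cryptokin sketch sets/F2.set --params params.json --out F2.priv
cryptokin compare child.pub F2.priv --params params.json
# {"public_id": "G1I0", "own_id": "F2", "status": "success",
#  "leakage_bits": 1536, "n_differing_elements": 58}   -> exit 0 (related)

cryptokin sketch sets/F0.set --params params.json --out F0.priv
cryptokin compare child.pub F0.priv --params params.json
# {"public_id": "G1I0", "own_id": "F0", "status": "failure",
#  "leakage_bits": 1536}                               -> exit 1 (unrelated)
```

The parent decodes the child's public sketch — recovering exactly the 58
elements by which the two hashed sets differ — while the unrelated founder,
whose symmetric difference exceeds 64, learns nothing but the failure.

## Scope

Inputs are assumed phased (unphased genotypes are rejected, not phased
internally).  Only single-base variants are encoded.  Kinship-coefficient
estimators, IBD-segment inference and pedigree reconstruction are out of
scope, as are formal security proofs and networked key exchange.
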
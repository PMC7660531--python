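# Methods

## Model and assumptions

`hemotyper` treats each blood-group system as a single diploid gene whose
alleles are fully described by base states at a catalogue of variable
positions (the ISBT view of KEL, FY, JK, YT, DO, CO, IN, DI and LW). An
individual's typing is the unordered pair of database alleles — the
diplotype — consistent with the observed pileup genotypes and with the
read-backed phase relationships between heterozygous sites. The model
assumes SNV-only alleles on a structurally normal gene: systems requiring
copy-number or hybrid-gene analysis (RH, MNS, ABO) are out of scope, as is
HLA typing (the allele-matching engine is generic, but no IMGT loader is
provided). Indels are not simulated, aligned or called.

## Allele database

Coordinates are 0-based half-open internally; cDNA labels follow HGVS
display conventions (`c.1` is the first CDS base, `c.-67` counts linearly
upstream of the CDS start, so promoter variants such as the Duffy GATA-box
SNV participate in typing exactly like exonic ones). Gene annotation is a
BED-like sidecar of CDS/UTR3 segments; the CDS is assumed to begin at the
first exon base (5′ UTR is modelled as upstream flank), and the last exon
may extend past the stop codon, which is how exonic post-stop variants are
recognised. Alleles store only their deviations from the reference allele;
the reference allele is the one whose state is the reference base
everywhere, synthesized as `<gene>*REF` when not listed. Multi-allelic
positions are supported (`alt` is a set) although the bundled catalogue is
bi-allelic throughout.

The bundled toy database covers the 14 SNaPshot-assayed positions of the
nine systems plus *SLC14A1* c.130G>A, the defining SNV of the weak Kidd
allele JK\*01W.01 — without it that allele would be indistinguishable from
JK\*01. Beyond the alleles those positions name directly, the catalogue
includes each gene's reference allele under its conventional ISBT name
(KEL\*02, FY\*01, JK\*01, YT\*01, DO\*01, IN\*02, CO\*01, DI\*02, LW\*05),
the complementary alt-bearing alleles KEL\*01 and DI\*01 so heterozygous
calls at those sites resolve, and FY\*02N.01 (GATA-box null on the FY\*02
background), which makes the classic Duffy cis/trans ambiguity — 
FY\*01N.01/FY\*02 versus FY\*01/FY\*02N.01 — representable and lets
phasing demonstrably resolve it. Gene references are synthetic sequences
(deterministically generated, fixed content) with a realistic layout:
450 bases of 5′ flank, a two-exon CDS separated by a 180-base intron, a
60–90-base in-exon 3′ UTR and 350 bases of 3′ flank. The 450/350 flanks
keep every catalogued position more than one fragment length away from the
gene ends, so simulated coverage at catalogued sites is not edge-depleted.
Real ISBT tables (hundreds to thousands of positions per system) load from
the same TSV format; the bundled content is a structural stand-in, not a
transcription of the licensed tables.

## Read simulator

The simulator emulates TruSeq-style 2×150 bp paired-end sequencing of one
gene: `round(depth × gene_length / (2 × read_length))` fragments, each
drawn from one of the two haplotype sequences by a fair coin, with
truncated-normal fragment lengths (default mean 300 bp, sd 50 bp, redrawn
to fit the gene — no wraparound) and uniform start positions. Errors are
i.i.d. substitutions at a configurable per-base rate (default 0.1 %, the
right order for Illumina after Q20 trimming); qualities are constant Q30
or linearly decaying to Q10 over the last 40 bases (the `decay` profile
exists to exercise the trimmer). One master seed drives deterministically
derived per-sample streams, so cohorts are byte-reproducible. What the
simulator does **not** model — indels, PCR duplicates, GC bias, chimeras,
whole-genome background reads, paralogous off-target sequence — bounds
what passing tests show: they validate the calling/phasing/typing logic
under clean mapping conditions, not robustness to alignment artefacts in
real genomes.

Because fragments start uniformly within the gene, interior positions see
somewhat more than the nominal fold-coverage (≈ depth × 300 / (L − 300)),
and positions near the ends see less; catalogued positions are interior by
construction (see above).

## Numerical and algorithmic choices

* **Quality trimming** uses the BWA partial-sum rule (trim at the 3′
  position maximising Σ(Q20 − q)), matching the semantics of the trimmer
  the preprocessing emulates, rather than naive consecutive-base trimming;
  a high-quality island inside a degraded tail is therefore trimmed too.
  Only the 3′ end is trimmed.
* **Adapter removal** takes the longest read suffix matching an adapter
  prefix with ⌊0.1·overlap⌋ mismatches, minimum overlap 3.
* **Built-in matcher**: 31-mer seed index over all gene references,
  staggered seed offsets plus a 3′ flush seed, ungapped extension, at most
  5 mismatches; the best placement wins and ties are reported
  multi-mapping and excluded from pileups. It guarantees exact placement
  of error-free simulated reads; production data may instead supply SAM/
  BAM from any aligner. No gapped alignment.
* **Pileups** count each template once: overlapping mates contribute a
  single observation per position, and mates disagreeing at a shared
  position contribute none. Bases below Q13 are excluded. Duplicate
  fragments are not collapsed. In the dense (whole-gene) pileup used by
  the novel-variant screen, mate overlap is resolved by clipping the
  later-starting mate.
* **Genotype bands**: with depth ≥ 5, minor fraction f = c₂/(c₁+c₂) over
  the two most frequent bases; f ≥ 0.2 → het, f ≤ 0.1 → hom, otherwise a
  no-call with reason `ambiguous_fractions`. The band edges are inclusive
  on the calling side (f = 0.2 is het, f = 0.1 is hom) and configurable.
* **Phasing** treats the template (both mates) as the phasing unit even
  when the reads do not physically overlap both sites; a strict
  single-read mode (`joint_mates=False`) is available for the literal
  reads-overlap interpretation. Edges need ≥ 2 concordant fragments and a
  ≥ 2/3 majority; ties split the component. Haplotype labels a/b are
  arbitrary and downstream typing is invariant under the swap.
* **Diplotype enumeration** is exhaustive over unordered allele pairs (at
  most tens per gene), so the production path coincides with a brute-force
  oracle; candidates are ordered lexicographically for deterministic
  reports. A no-call constrains nothing, but forces `not_defined` when the
  surviving candidates disagree at the uncovered position; no-calls at
  non-discriminating positions are ignored. A called genotype outside
  every allele combination yields `not_defined` with an "unreported
  polymorphism" annotation (feeding the novel-variant screen) rather than
  an error.
* **Reliability** is advisory metadata: a gene is `reliable` only when its
  estimated depth (mapped reads × 150 / gene size) is strictly above 15×;
  15.0× exactly is `low_depth`. Results below the threshold are still
  reported. Genome-equivalent depth uses the fixed genome size
  2,867,437,753 bp. Gene depth uses the plain gene length; an effective
  (repeat-masked) size may be supplied by the caller.
* **Novel-variant screen**: "occurrences" means distinct carrier samples,
  not supporting reads; carrier status uses the same genotype caller as
  typing so a lone erroneous read never creates a carrier. One record per
  (position, alt) pair. Non-exonic positions are reported with region
  `intron` (the report does not distinguish flank from intron).
* **Concordance**: ambiguous WGS typings score as unresolved (nd), truth
  nd records are excluded entirely, and percentages are rounded half-up —
  per-polymorphism figures at one decimal, headline figures also at
  integer precision, reproducing the conventional mixed presentation
  (99.5 % typed versus 93 % overall).

## Problem sizes in tests and the acceptance script

The simulation studies run at desk scale against the toy database:
genotype/typing recovery uses 200 nine-gene samples at 30× with 0.1 %
error (the acceptance script uses 100); phasing recovery uses 100
error-free Duffy replicates; the depth-grid study uses 400 Kidd samples
per depth in {2, 5, 10, 15, 30} at 1 % error (400 total across
{5, 10, 15, 30} in the script); the novel-variant study uses 50 cohorts
(script: 30) of 10 samples each. These sizes keep every study's Monte
Carlo error comfortably inside the asserted margins while the full suite
runs in well under a minute.

## Known limitations

* SNV-only semantics: indels, CNVs and hybrid genes are out of scope.
* The toy references are synthetic; nothing here validates mapping
  specificity against the real human genome (paralogy, repeats).
* PolyPheMe-style het/hom fraction thresholds are not published for the
  emulated workflow; the 0.1/0.2 band is this package's own documented
  default and is configurable.
* The effective (repeat-free) gene size used by some depth reports is
  accepted as user input, never computed.
* Statistical hypothesis testing on read-count differences between typing
  statuses is deliberately not included; `depth_by_status` emits the
  grouped summaries such tests would consume.
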
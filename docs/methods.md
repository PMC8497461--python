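# Methods

This note records the models, conventions and design choices behind each
stage of the pipeline, what the simulator does and does not emulate, and
the numerical details a user should know before trusting the outputs.

## Synthetic genomes (`ltrkit.simulate`, `ltrkit.family`)

**Family reference.** `default_family()` builds a fully synthetic but
internally consistent reference bundle, dimensioned like a young plant
Copia family: 775 bp LTRs (starting TG, ending CA), a 3,861 bp noncoding
internal sequence (nis), a 4,155 nt group-1 reference ORF carrying the
four domain motifs (GAG, GAG_PRE_INT, INT_CORE, RT — 45/40/55/65 aa
consensus stand-ins, clade-labelled "Angela"), and a group-2 variant
derived by inserting a T between nucleotides 66 and 67 of the group-1 ORF.
The insertion frameshifts the original start; an in-frame Met pinned at
codon 29 makes the 4,071 nt restart ORF the longest reading frame of the
variant, reproducing the diagnostic 84 nt N-terminal truncation. The
builder verifies both ORF lengths by a six-frame scan and retries
deterministically over sub-seeds until the constraint holds, so the bundle
is a pure function of its seed. The internal region is framed by three
conserved noncoding segments — PBS_ATG (300 bp, between 5′ LTR and
ORF/nis), 3_ATrich (250 bp at 14% GC) and 3_cons (300 bp) — whose offsets
are recorded in the region annotation.

**Substitution process.** Each planted copy of age T years is mutated by a
two-rate process: the number of substitutions per sequence part (each LTR
copy and the internal region, independently) is Binomial(L, 1 − e^(−μT)),
which keeps the per-site expectation exact rather than linearized; sites
are drawn without replacement; given an event, a transition is chosen with
probability κ/(κ+2) and each transversion with probability 1/(κ+2) — the
event frequencies the Kimura 2-parameter model assumes. Defaults
μ = 1.3 × 10⁻⁸ /site/year and κ = 2. The two LTR copies therefore diverge
by 2μT per site in expectation, which is exactly the quantity the dating
stage inverts.

**Purifying selection on coding copies.** Fully coding (`orf_full`) copies
are aged with a nonsense-rejection constraint: a substitution that would
create an in-frame stop codon inside the realized reading frame is
redrawn. Without it, roughly a third of 0.2-My-old copies acquire a
premature stop and would no longer be fully coding — autonomous copies
observable as such in a real genome are precisely those that escaped
disabling mutations, so the constraint emulates the conditioning inherent
in the class definition. Partially coding copies are built by knocking a
premature stop into the middle of the realized reading frame (located per
group, since the group-2 frame is shifted), leaving each surviving
fragment with two of the four domains; degenerate copies get a randomized
internal core between the conserved flanks.

**Insertion mechanics.** Elements are inserted at point positions chosen
on the background coordinate system; the `tsd_length` host bases at the
insertion point (default 5, configurable 4–6; the source study does not
report TSDs for this family) are duplicated to flank the element. Genes
(single-CDS models, default 100 per Mb, 3 kb long) are placed first;
insertion points fall in gene bodies or 5 kb flanks with relative weight
`gene_bias_weight` (default 5, emulating the family's observed bias toward
gene-dense arms; weight 1 gives unbiased placement). Strand is random;
minus-strand elements are inserted as reverse complements. Genome length
is conserved exactly: |output| = |background| + Σ(|element| + tsd). Truth
records store final coordinates (excluding TSDs), class, group, age, TSD
sequence and genic context.

**What the simulator does not emulate:** nested insertions, solo LTRs
(recombination products), indel mutation, sequencing or assembly error,
realistic gene structure (introns/UTRs), and genome-scale repeat
landscapes. Passing recovery tests therefore demonstrates correctness of
the mining/classification/dating logic under clean substitution-only
divergence, not robustness to assembly artifacts.

## Mining (`ltrkit.mining`)

The scan is seed-and-extend: exact 12-mer seeds anchor candidate windows
(query length ± 100 bp margin, overlapping windows merged), each window is
aligned locally against the oriented query (match +1, mismatch −1, gap
open −4, extend −1), and a hit is reported when identity ≥ 0.90 (matches
over aligned columns) and query coverage ≥ 0.70 (aligned query fraction).
Chromosomes ≤ 20 kb with no seeds fall back to direct windowed alignment,
so heavily diverged toy fixtures are still scanned exhaustively. Both
strands are searched by default; minus-strand hits are reported in
plus-strand coordinates. Overlapping same-strand hits keep the higher
score.

Pairing is greedy left-to-right: each unpaired hit takes its nearest
downstream same-chromosome, same-strand partner whose gap (end of 5′ hit
to start of 3′ hit, i.e. the inter-LTR distance) lies in [2,000, 10,000]
bp inclusive. Greedy nearest-partner matching maximizes the number of
disjoint pairs under an interval-window constraint and makes the leftmost
choice on ties; an alternative reading where the bounds constrain the full
element span is available via `gap_is_internal=False`. Extraction realizes
the element span [ltr5.start, ltr3.end), detects the TSD as the longest
identical flanking k-mer (k = 6 down to 4), and records the
global-alignment identity of the two LTR copies.

## Classification (`ltrkit.classify`)

Minus-strand elements are reverse-complemented before analysis. The
longest ATG-to-stop ORF (≥ 30 codons, six frames, ties to the 5′-most
plus-strand start) is scanned against the four domain motifs by local
BLOSUM62 alignment (gap open −11, extend −1); a domain is present when the
score reaches 0.60 of the motif's self-score — a threshold that separates
the packaged motifs from shuffled controls by a wide margin. Four domains
→ `orf_full`; one to three → `orf_partial`; otherwise the internal region
is aligned locally against the nis reference and called `nis` at identity
≥ 0.80 over ≥ 0.50 of the nis length (both thresholds are package choices,
exposed in `ClassifyThresholds`; the source study reports none). Remaining
elements are `other`.

Group assignment compares semi-global edit distances (edlib, infix mode)
of the internal region against the two group references; because the
references differ only by the diagnostic T insertion, the copy's own
substitutions penalize both references equally and the indel decides the
call deterministically (ties favour group 1). Family assignment follows
the domain-majority rule: a clade label is returned only when its
frequency among domain hits strictly exceeds 0.5, else "unknown".

Region identities (PBS_ATG, 3_ATrich, 3_cons) locate each region by local
alignment against the canonical region sequence (requiring ≥ 30% identity
over ≥ 50% of the region, else the region is flagged as not located) and
report the percent identity of the global alignment of the two located
segments, counting gap columns as mismatches.

## Dating and phylogeny (`ltrkit.dating`)

LTR pairs are globally aligned (same DNA scoring as the scan; inputs
< 50 bp are rejected) and the Kimura 2-parameter distance is computed over
gap-free columns: K = −½ ln(1−2P−Q) − ¼ ln(1−2Q), raising a saturation
error when either logarithm is undefined. Age = K/(2μ): the factor 2
follows the standard LTR-dating convention (both LTRs accumulate
substitutions independently after insertion); the divisor is configurable
for comparison with studies that divide by μ.

Age and Ks distributions share one estimator: a Gaussian KDE with
Silverman bandwidth evaluated on a 512-point grid clipped at zero, with
modes reported as local maxima above 10% of the peak, ascending. Cohorts
of fewer than five values fall back to a histogram (logged); zero-spread
samples return a point mass. A caveat documented here because it is
visible in calibration runs: for a cohort planted at a single age, the
per-copy mismatch counts are small integers (≈ Poisson(4) at 0.2 My on
775 bp LTRs), so the estimated ages form discrete atoms and the KDE mode
scatters around the true age by roughly one atom spacing (± ~0.05 My at
0.2 My, n = 200) with a mild low-side skew bias.

The family tree is UPGMA over p-distances (mismatches over gap-free
columns of pairwise global alignments — a deliberate replacement of the
usual multiple alignment, equivalent at the low divergences of a young
family). Agglomeration joins the minimum-distance pair at height d/2 with
size-weighted average updates; ties break on the lexicographically
smallest leaf ids, so output is deterministic; the result is ultrametric
by construction and serialized as newick.

## Distribution statistics (`ltrkit.distribution`)

Features are assigned to the window containing their midpoint (half-open
windows, boundary midpoints to the right), which makes window counts
conserve the feature total exactly — the reason midpoint assignment was
chosen over overlap-weighting. Track correlation is Pearson's r (undefined
and rejected for constant tracks). The gene-proximity ratio counts an
element as genic when its midpoint lies inside a gene body or within
`flank_bp` (default 5,000 bp — a package choice; the source study
delegated context calls to an annotation tool without stating distances).

## Ka/Ks (`ltrkit.kaks`)

Codon alignment translates both CDSs (trailing partial codons trimmed,
internal stops rejected), globally aligns the proteins under BLOSUM62 and
back-threads the alignment to codons. NG86 counting: each codon position
contributes (synonymous sense changes)/3 to S and the remainder —
including changes to stop codons — to N, so S + N = 3 per ungapped codon
exactly; differences between codons are averaged over all minimal mutation
pathways, excluding pathways through stop codons (all pathways are used in
the rare case every one is blocked); proportions are corrected by
d = −¾ ln(1 − 4p/3), with p ≥ ¾ flagged as saturated. NG86 was chosen as
the Ks method on its own merits (exact, assumption-light at moderate
divergence); the per-pair `method` field records it. Ks values above 3 are
excluded from density estimation as saturated noise. Genome-scale pair
selection (synteny chains) is out of scope; pairs are supplied explicitly.

The Ks calibration generator builds coding pairs exclusively from
fourfold-degenerate codon boxes whose first two positions are strictly
nonsynonymous under single changes (Ala, Gly, Pro, Thr, Val, Ser), so each
codon carries exactly one synonymous site — its third position — and a
Jukes–Cantor resampling of third positions at rate d gives a cohort whose
true Ks equals d exactly. On such cohorts the NG86 + JC estimator is
unbiased within sampling error at Ks 0.1 and 0.8.

## Gene triage (`ltrkit.triage`)

Criteria, with thresholds fixed at their published defaults: (1)
UniProt/NR hit with E ≤ 1e-80 and identity ≥ 80%; (2) congeneric-proteome
hit with E ≤ 1e-80, identity ≥ 90%, length coverage 60–140%; (3) domain
hit with E ≤ 1e-50; (4) TPM > 0. TE precedence (TE-library similarity or a
TE-related product name) is evaluated first. "Fulfilling (1) to (4)" is
read as the conjunction of all four by default; because the phrasing is
ambiguous, an alternative mode `any_similarity_plus_expression` —
(1) or (2) or (3), and (4) — is provided. The LC→HC rescue requires an
Araport-tagged hit with E ≤ 1e-10, identity ≥ 25% and length coverage
60–140% ("length ≥ 60%" and "coverage ≤ 140%" are read as the two bounds
of the same length-coverage statistic, matching criterion 2's usage), and
is idempotent. Transcript-model filtering keeps sense-oriented models
mapped at 95–105% of their length and ≥ 99 nt ("less than 99 nt excluded"
read strictly), applied before locus resolution; each locus then keeps one
model with long-read (isoseq) support ranked above length, and length
breaking ties within a source.

## Problem sizes and tolerances

The test suite and acceptance script run on deliberately small instances
chosen to make each statistical check well-powered while keeping a full
run to a couple of minutes on one CPU: two 200–300 kb chromosomes with
~36 planted copies for mining/classification recovery (recall, precision
and class+group accuracy all ≥ 95% observed at 36/36), 200-element
cohorts for dating calibration, 300-pair × 300-codon cohorts per Ks
component, and n ≤ 6 matrices for exact UPGMA oracle comparison. Numeric
equivalence checks (K2P closed form, NG86 brute-force oracle, alignment DP
oracles) are asserted at 1e-9–1e-12; statistical checks use 3–4 standard
errors or the recovery bands stated in the tests.

## Known limitations

* The scan is tuned for high-identity (≥ ~85%) family copies; it is not a
  de-novo LTR finder and will miss solo LTRs and nested elements by design.
* K2P dating assumes neutral post-insertion divergence and a single
  substitution rate; gene conversion between LTRs (which rejuvenates
  apparent ages) is not modelled.
* The domain scan uses packaged consensus motifs, not profile HMMs; it
  classifies relative to the supplied family bundle only.
* p-distance UPGMA underestimates deep divergences; the tree is meant for
  young-family structure, not deep phylogeny.
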
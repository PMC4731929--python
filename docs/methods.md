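# Methods

This note documents the models and procedures implemented in `aluexon`,
the parameter defaults and why they hold, the design choices made where
the design was genuinely open, and what the synthetic study does and does
not establish about real data.

## Coordinates and gene models

All internal coordinates are 0-based half-open on the forward genome
strand; GTF (1-based closed) and RepeatMasker `.out` (1-based inclusive)
are converted at the I/O boundary, and minus-strand sequence operations
reverse-complement at fetch time. A transcript model carries its exons in
ascending genomic order plus the genomic CDS span (start codon through
stop codon); non-coding transcripts carry no CDS and are excluded from
coding analyses with an explicit signal.

## Identifying Alu-derived internal exons

An internal (cassette) exon — neither first nor last in its transcript —
is called Alu-derived when a **single** repeat copy covers at least
**25 bp** of it and **more than half** its length (strict inequality).
When several repeats overlap one exon, only the copy with the largest
intersection is considered, and the thresholds apply to that copy alone;
summing across copies would let two marginal fragments masquerade as a
predominant origin. Records are per (exon, transcript) pair; exon
coordinates deduplicate pairs when a unique-exon count is needed.
Transcript and repeat inputs with completely disjoint chromosome name
sets (e.g. `chr1` vs `1`) raise immediately, listing the offending names,
since silent zero-overlap results are the classic failure mode here.

## Region and NMD classification

An exon overlapping the CDS span by ≥ 1 bp is classified CDS; this
any-overlap rule is the permissive reading (the alternative — requiring
full containment — silently drops exons straddling a UTR/CDS boundary),
and such straddling exons are flagged per record. Exons entirely outside
the CDS fall in the 5' or 3' UTR by strand.

The inclusion isoform is built by splicing the cassette exon into the
mature mRNA in genomic order and translating from the annotated start
codon to the first in-frame stop; an exon length not divisible by 3
shifts the downstream reading frame, and translation simply continues in
the shifted frame (a frameshifted stop may land anywhere downstream,
including the terminal exon). If no stop is reached the record is flagged
stop-lost rather than dropped, and classified NON_PTC with a warning.

The NMD rule: the transcript is PTC when the last exon–exon junction lies
more than 50 nt downstream of the stop codon. The stop position is
measured just past the stop codon's last base; the rule's strictness
means a stop exactly 50 nt upstream of the junction is NON_PTC. The
classification is invariant to adding 5'UTR exons, which shift the stop
and the last junction equally.

## Junction libraries, read matching, Ψ

Each cassette exon defines three junction sequences of 54 nt (27 + 27):
upstream inclusion, downstream inclusion, and skipping. Flanks or exons
shorter than 27 nt truncate their segment and flag the library. Reads are
trimmed to a fixed prefix (50 nt for RNA-seq, 30 nt for Ribo-seq
footprints, whose raw length is 36 nt), then matched ungapped at every
offset where the read covers the splice boundary with at least one
nucleotide on each side. A read counts iff its best alignment has ≤ 2
mismatches and exactly one junction in the whole library attains that
minimal mismatch count; ties are discarded as multi-mapped. The
midpoint-overlap rule is the documented stand-in for whatever boundary
handling a seed-and-extend aligner would apply; with 54-nt junctions and
≥ 28-nt reads it is automatic and only bites for truncated junctions.

The inclusion level is Ψ = I/(I+S) with I = (UJC+DJC)/2 and S = SJC.
Averaging the two inclusion junctions corrects the two-junction versus
one-junction count imbalance; no length normalisation is applied because
all junctions have equal mappable extent by construction. Ψ is undefined
when I + S = 0, and an estimate is "covered" when some junction has
≥ 10 reads. Screens: Ψ ≥ 0.33 in ≥ 1 covered sample (high inclusion), and
a pairwise differential screen calling an exon when some sample pair
shows |ΔΨ| ≥ 0.10 at BH FDR < 0.10, with a two-sided Fisher exact test on
the 2×2 table of rounded-half-up I versus S per sample. This simple
count-based screen is a declared stand-in for a full likelihood-based
differential-splicing model (out of scope) and is not claimed equivalent;
the BH family is all (exon, pair) hypotheses jointly, the conservative
choice given that the original's family definition is unstated.

## Ribo-seq evidence

Footprint counts over the same junction library yield a footprint Ψ.
Per exon, flags are set only when both assays pass the coverage gate:
nonzero footprint inclusion, strong translation (Ψ_ribo ≥ 0.15, exposed
as a parameter), and higher-in-footprints (Ψ_ribo > Ψ_rna). Enrichment of
strong translation among candidate coding exons over NMD-inducing
controls is a one-sided (greater) Fisher exact test. Stop-codon
truncation of footprint signal is a property of the simulated data (no
footprints are generated on junctions 3' of the relevant isoform's stop),
not an additional filter — the phenomenon is observed, not enforced.

## Peptide mapping and the negative-control FDR

The protein space holds a background proteome plus each candidate exon's
inclusion-isoform translation annotated with the exon's amino-acid span
and the two junction positions in protein coordinates. An amino acid
whose codon straddles an exon boundary is assigned to the exon span
(inclusive rule), so a peptide covering it plus at least one full flank
residue counts as junction-spanning; a peptide ending exactly at a
junction is exon-body. Matching is exact string matching (no I/L
equivalence, no PTM awareness): peptides enter as database strings.
Peptides shorter than 6 residues are dropped; peptides occurring at more
than one location anywhere in the space are dropped — in the synthetic
study multi-mapping arises exactly as in reality, from distinct
exonization events sharing near-identical Alu sequence.

The FDR bound: with h_c hits among n_c candidates and h_0 hits among n_0
negative-control (NMD-inducing) exons, the expected false positives are
round(n_c · h_0/n_0) (half-up) and the FDR upper bound is that count
divided by h_c. This is an upper bound because it assumes every control
hit is false. With the published counts (262, 85, 649, 47) it gives
19 expected false positives and a 22% bound.

## Differential A-to-I editing

Input: per-site edited/unedited counts for nine libraries (EV, short
isoform, long isoform × 3 replicates). Filters: at least one library with
≥ 5 edited reads, and coverage in at least one replicate of every group.
Merged levels pool the three replicates (level = Σe/(Σe+Σu)); global
group comparisons use sites with pooled coverage ≥ 50 in both groups and
a **paired** two-tailed Wilcoxon signed-rank test across the shared sites
(the comparison is of the same sites between conditions; exact null for
≤ 25 pairs, normal approximation with continuity correction beyond).

Differential editing per isoform: replicate k of the treatment is
Fisher-tested (two-sided) against **EV replicate k** — index pairing
preserves three independent tests and hence 6 df in Fisher's method; a
pooled-EV pairing is available as an option since the original pairing is
unstated. Replicate pairs without coverage contribute p = 1 and are
flagged; p-values that underflow to 0 are floored at the smallest
positive double and flagged. Combined p-values are BH-corrected per
isoform across all retained sites (the family the per-isoform FDR
implies); differential means q ≤ 0.10. Site classification: COMMON when
both isoforms' q ≤ 0.10; high-confidence isoform-specific when one
q ≤ 0.10 and the other ≥ 0.90; low-confidence isoform-specific when the
other q falls strictly between; otherwise not differential. The rule is
symmetric under swapping the isoform labels.

## Statistical kernels

`aluexon.stats` wraps scipy/statsmodels with the package's contracts:
Fisher exact (two-sided by the point-probability rule — tables no more
likely than the observed one — matching mainstream statistical software),
Fisher's method (χ² = −2Σln p on 2k df; rejects p ≤ 0, leaving underflow
policy to callers), BH step-up with monotonicity, and the Wilcoxon
signed-rank variant described above. Extreme p-values are reported to two
significant figures in output tables. The test suite checks every kernel
against brute-force enumeration oracles (hypergeometric enumeration over
all tables at fixed margins; exhaustive sign-flip enumeration).

## The synthetic study

`simulate_genome` builds one gene per chromosome: a 5'UTR exon (120 nt),
2–4 coding exons (90–180 nt) whose concatenation is ATG + non-stop codons
+ TAA, a terminal exon carrying the stop and 150 nt of 3'UTR, introns of
200–400 nt, and 500-nt flanking spacers; roughly half the genes are
minus-strand. A bundled 300-nt synthetic Alu-like consensus (invented
sequence with Alu-like length and composition; subfamily labels
AluSx/AluY/AluJb are simulation metadata, not sequence-derived) is
inserted into introns with probability 0.85, and 70% of insertions are
exonized. CDS events insert at codon boundaries and split into
event types: coding (length a multiple of 3, internal stops repaired),
stop-carrying (a planted in-frame TAA), and frameshifting (length ≢ 0
mod 3); 5'UTR and 3'UTR events insert around the CDS, the latter into a
split 3'UTR whose host stop-to-junction distance (30 nt) keeps the host
itself NMD-immune. Ground truth (region, frame, NMD fate via an
independent generator-side translation of the assembled mRNA, true Ψ per
tissue from Beta(2,2), translation factor) is recorded per event; the
repeat track covers exactly the inserted copies, in both `.out` and BED
dialects. Two planted controls exercise the negative space: exons
overlapping their Alu by only 24 bp / 40% (must not be found), and event
pairs sharing an identical codon-aligned exon slice (whose body peptides
must multi-map and be rejected).

Junction counts sample each junction independently:
UJC, DJC ~ Binomial(depth, ψ·t) and SJC ~ Binomial(depth, 1−ψ), with
depth ~ Poisson(200) read opportunities per junction and t the event's
translation factor (1 for RNA and for translated isoforms, 0.3 for
NMD-suppressed inclusion isoforms in the footprint assay). Under this
equal-mappable-length model the averaged-junction estimator is consistent
for ψ; an early design that split a single inclusion draw between the two
inclusion junctions made the estimator structurally biased and was
replaced. `noiseless=True` emits exact float-valued expectations, the
noiseless limit in which Ψ̂ equals planted ψ to machine precision and the
splicing funnel is exactly recoverable for any seed. Reads can be
materialised from the planted junction sequences (windows covering the
boundary) to exercise the matcher end to end.

The editing simulator draws per-site baselines from Beta(2, 6) (mean
0.25, right-skewed as editing-level distributions are), shifts each
condition on the logit scale (δ = 1.5 for affected sites, 0 for EV and
null sites), draws replicate coverage from a negative binomial (mean 100,
dispersion 10) and edited counts binomially. Everything is a
deterministic function of the seed.

What the synthetic study does **not** emulate: sequencing errors and
quality scores, positional read-start bias, fragment-length effects,
alternative transcript structures per gene, real Alu subfamily sequence
divergence, P-site geometry in footprints, and covariance between
editing sites. Passing tests therefore demonstrate the correctness of
the algorithms and their calibration under the stated statistical model,
not performance on real libraries.

## Problem sizes and numerical choices

Default study sizes keep the full test suite and the acceptance script
comfortably within a desktop run: 30 genes (≈ 16 planted events), depths
of 200–2000 junction reads, 100 replicates for estimator-bias checks, 50
simulation runs of 200 null sites for the false-positive calibration, and
100 effect + 100 null sites at coverage 200 for power. Ties in read
matching are discarded, rounding in the differential-splicing table and
the FDR projection is half-up, empty-margin 2×2 tables in screens yield
p = 1 (no evidence of difference) rather than an error, and all
randomness flows from a single integer seed through independent
per-stage streams.

## Known limitations

The differential-splicing screen is a count-based stand-in, not a
replicate-aware likelihood model. The peptide-uniqueness universe is the
built protein space, not a full proteome with all annotated isoforms; a
host gene's skipping isoform is not a separate entry, so flank-only
peptides remain unique but never count as exon evidence. Splice-site
strength enters only as externally computed log2-odds scores (the
fold-change arithmetic is provided; the scoring model is not). Editing
analysis ingests count tables; it performs no read-level editing
detection or de-novo site discovery.
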
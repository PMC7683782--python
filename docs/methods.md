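# Methods

This note documents the models, conventions and design choices behind
`neopept`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the open design space was resolved.

## Coordinates and formats

All internal intervals are 0-based half-open on the genomic forward
strand; VCF (1-based) and GTF (1-based inclusive) coordinates are
converted on ingestion and back on output, so VCF→internal→VCF is the
identity. BEDPE intervals are taken as 0-based half-open as the format
defines. The junction dialect — which the upstream formats leave open —
is fixed as: for a `+`-strand 5′ partner the junction-adjacent base is
`end5 − 1` (end exclusive), joined to `start3` (start inclusive) for a
`+`-strand 3′ partner, with the strand-symmetric opposite ends otherwise.
Fusion gene labels accept both `GENE5--GENE3` and `GENE5>>GENE3`.
Unknown GTF attributes are ignored. Alignments are read as SAM text;
BAM/CRAM are out of scope so fixtures stay plain text.

## Consensus calling

SNVs are merged on the exact trimmed (chrom, pos, ref, alt) key — no
fuzzy position matching, so the merge is reproducible and order-invariant
— and emitted when at least `min_support = 2` distinct callers report the
key. Duplicate records from one caller count once. Indels come from the
single designated source (Strelka in the default study) without a
consensus requirement. Both paths require PASS filter status by default
(`require_pass`); the indel case is configurable as an explicit option,
and the SNV case follows the same rule for consistency.

The HLA consensus applies a 2-of-3 vote across tumor DNA, normal DNA and
tumor RNA call sets. Homozygous (repeated) calls within one source count
once toward the vote; loci outside A/B/C/DPA/DPB/DRB are dropped. A locus
may end up with one allele (apparent homozygote) or none (no agreement);
downstream stages simply see fewer alleles.

## Effect annotation and mutant proteins

Coding effects are derived directly from the GTF + FASTA (no external
annotator): each variant is mapped into spliced-CDS coordinates of every
coding isoform it edits, strand-aware (alleles are reverse-complemented
onto the transcript strand; minus-strand insertions are re-anchored to
the transcript-orientation insertion point). Indels spanning a splice
boundary are skipped with a warning rather than guessed. A reference
mismatch between the variant and the genome is a hard error naming the
locus.

Mutant proteins are built by editing the spliced CDS and re-translating.
The first frameshift switches to novel-frame translation that may run
past the annotated stop into the 3′ UTR and, if needed, past the
transcript end into genomic sequence, until a stop codon or `max_tail`
(default 100) novel residues — the tail threshold is user-facing because
no biological default exists. Translation uses the standard nuclear
codon table throughout; the toy mitochondrial contig carries no coding
genes, so the mitochondrial table is not needed.

Per-residue provenance marks the codons an edit touched (for a
frameshift, everything from the shifted residue on). The reported
`mutant_positions` of a peptide window are the positions where mutant and
wildtype actually differ, which for in-frame indels includes the
register-shifted stretch inside the window.

## Chaining, phasing, windows

Chaining distance is measured in spliced-CDS coordinates, not genomic:
the 27/30/45 bp windows equal 3·n and encode peptide proximity, which
splicing would otherwise distort. Grouping is single-linkage and
transitive, independent of input order, and computed per n, since the
window constants are per n; groups that coincide across n merge into one
region with all three peptide lengths.

Phasing evidence is counted per adjacent event pair from RNA reads
covering both positions: a read with both alternate alleles is cis, one
alternate plus the other reference is trans, anything else is
uninformative. A pair stays chained iff `cis ≥ min_cis` (default 1) and
`cis ≥ trans`. With RNA provided, a pair with zero informative coverage
splits — the conservative reading of "confirm co-expression". With no RNA
input at all, groups stay chained but are labeled `no_evidence`, so an
RNA-less run still produces multi-event regions rather than silently
discarding chaining. Base-level evidence is defined for SNV–SNV pairs;
pairs involving an indel have no cis evidence and split.

A region's window runs (n−1) residues upstream of the first mutant
residue through (n−1) past the last, clipped at the protein ends; the
wildtype peptide is the same coordinates in the unedited protein and is
absent for frameshift tails and fusions. Un-clipped single-missense
windows are therefore exactly 17/19/29 residues for n = 9/10/15. When
one variant hits several isoforms with identical peptide context, the
contexts deduplicate into one region whose TPM is the sum over the
merged isoforms.

## Fusions

Filters, each independently toggleable: both partners on the
mitochondrial contig (`mito_mito`); both biotypes starting `IG_`
(`ig_ig`); same chromosome with breakpoints within 500 kb
(`readthrough`, threshold configurable, strand ignored — distance is
between the two junction-adjacent bases); 5′ partner annotated lincRNA
(`linc_5p`). A fusion can carry several reasons but is reported once;
an unresolvable gene label is always rejected.

Junction translation takes the last (n−1)·3 coding bases before the 5′
breakpoint, extended downward to the containing codon boundary so the 5′
frame is preserved when the junction falls mid-codon, joined to
(n−1)·3 bases starting at the 3′ breakpoint (spliced exonic sequence when
the breakpoint is exonic, raw genomic otherwise), translated and
truncated at the first stop. An in-frame, un-truncated junction therefore
yields exactly 2·(n−1) residues (16/18/28). No region is produced when no
codons precede the junction (5′ UTR or non-coding 5′ partner,
`utr_5p`); an intronic 5′ breakpoint is an explicit unsupported case
(`intronic_5p`) since resolving it would require a splice-graph model.
Provided junction sequences take precedence over annotation inference and
are assumed to start in frame.

## Binding

Windows of length n covering ≥ 1 mutant position are routed by class
(9/10-mers to class I alleles, 15-mers to class II; HLA-DP is assayed as
an alpha/beta pair and skipped with a warning when only one chain reached
consensus). The consensus percentile is the median of the per-method
percentiles returned by the predictor plug-in; the acceptance cut
`percentile ≤ 5.0` is inclusive and applied to the consensus. Wildtype
counterparts are assayed only for accepted mutant calls, halving
predictor load and mirroring the two-stage assay design.

The bundled mock predictor hashes (peptide, allele, seed) with BLAKE2b
into three pseudo-method percentiles, uniform on [0, 100] and identical
across platforms; in motif mode, peptides containing a planted anchor
motif score below 1.0 so fixtures always contain binders. It exists to
make the pipeline testable end-to-end; its scores carry no biology, which
is precisely why planted-truth checks can be exact.

## Ranking

Candidates enter ordered by the best (lowest) percentile of a contained
call, ties broken by more accepted calls then id. Feature scores are
within-run empirical quantiles, `(average-tied rank − 1)/(m − 1)` (0 for
a single candidate): self-contained, scale-free (monotone transforms of a
feature change nothing, so TPM needs no log), and degenerating gracefully
to 0.5 under full ties. This replaces score functions fit on external
cohort distributions, which cannot be reproduced from a standalone
package; the score function is swappable if calibrated curves exist.
Boosts are static across iterations. Each of the three iterations sets
`new_rank = old_rank · (1 − boost)` from the current integer position and
re-sorts (ties by better best-percentile, then id) — re-sorting between
iterations is the interpretation under which iterating matters at all.
Weights live in [0, 1] with sum ≤ 1, so boosts stay in [0, 1] and ranks
stay non-negative. The `nwt` feature is counted and reported but carries
default weight 0 for class I, matching the pseudocode's sum exactly.

## Synthetic study design

The fixture generator emulates every input at toy scale with fixed planted
truth: a 6 kb main contig carrying five coding genes (one spliced, one
minus-strand, one expression-silent), a lincRNA and two IG genes; a 604 kb
contig whose four small genes realize readthrough distances of exactly
200/400/500/600 kb; a mitochondrial contig; and two fusion contigs whose
junctions encode the printed example contexts (`RFVQGKDWG·V·KKFIRRDFL`
for the F133V missense; `DNSKMALNS|EALSVVSED` and the early-stop
`DNSKMALNS|ELS` junctions). Planted variants cover the caller-support
spectrum (5-caller, 2–3-caller, 1-caller), a synonymous call, an in-frame
insertion, a dual-frame-designed 2 bp deletion whose shifted frame stops
after exactly 7 novel residues, and three chained SNV pairs with
cis (5/0), trans (1/3) and zero-coverage read plans. Proteins use a
cyclic 20-residue filler with planted contexts overlaid, and one codon
per amino acid, so all nucleotide encodings are byte-stable; intergenic
sequence comes from the seeded RNG. The same seed yields byte-identical
files; changing the seed changes the noise but not the planted design.

What the toy study does *not* emulate: read errors, coverage variation,
tumor heterogeneity, realistic gene structure or binding biology. Passing
tests therefore demonstrate the correctness of the bookkeeping —
coordinates, translation, chaining, filtering, ranking arithmetic — not
predictive performance on real tumors.

Problem sizes were chosen so the full suite and the end-to-end run finish
in seconds on one core: ~30 planted raw calls, 20 fusions, 12 regions,
a few hundred peptide:allele assays; the translation oracle runs 200
random transcripts and the ranking oracle 100 random tables.

## Pipeline mechanics

Stages write TSV boundaries (`consensus_variants.tsv`, `iars.tsv`,
`epitope_calls_{I,II}.tsv`, `ranked_{I,II}.tsv`, plus fusion-rejection and
phasing tables) into the output directory and are skipped on re-run when
the output is newer than all inputs; a re-run is a byte-level no-op. The
manifest records version, seed and all options — with the same inputs it
suffices to reproduce the run byte-identically. All iteration orders are
sorted and the only randomness is the seeded mock predictor, so outputs
are deterministic by construction.

## Known limitations

Single-nucleotide phasing evidence only (no indel-aware phasing, no
read-pair co-phasing); no splice-graph inference for intronic fusion
breakpoints; no proteasomal processing, TAP transport or immunogenicity
modeling; the empirical-quantile score functions are within-run, so
boosts are comparable within one sample, not across cohorts.
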
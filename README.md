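# neopept

Tumor neoepitope candidate discovery from pre-computed per-patient calls.

Somatic mutations create tumor-specific peptides ("neoepitopes") that the
patient's MHC molecules may present to T cells, making them attractive
personalized-immunotherapy targets. `neopept` implements the bespoke
computational stages that turn standard upstream outputs — per-caller
somatic VCFs, fusion BEDPE calls, a GTF/FASTA reference, isoform TPM and
per-source HLA typing — into a ranked list of candidate *immunoactive
regions* (IARs), the contiguous mutant peptide contexts from which
candidate 9/10/15-mers are enumerated. It is aimed at
immuno-bioinformaticians who already run variant callers, fusion callers
and expression quantifiers and need the tested glue between those calls
and a binding predictor.

## What it computes

1. **Consensus calling.** SNVs advance when ≥ 2 of the 5 callers agree on
   the exact normalized (chrom, pos, ref, alt); indels pass through from a
   single dedicated source. The HLA haplotype keeps every allele called by
   ≥ 2 of 3 sources (tumor DNA, normal DNA, tumor RNA), restricted to
   HLA-A/B/C (class I) and HLA-DPA/DPB/DRB (class II).
2. **Translation.** Expressed (TPM > 0) coding events are injected into
   the transcript: SNVs and in-frame indels in place; frameshifts are
   translated in the shifted frame until a stop codon or a 100-residue
   tail. Events within 27/30/45 bp of each other in spliced-CDS
   coordinates (for 9/10/15-mers; 3·n bp) are chained into one IAR and
   phased with RNA reads — a pair stays chained only when cis reads ≥ 1
   and cis ≥ trans. The IAR spans (n−1) residues on each side of the
   mutant stretch; fusions contribute (n−1)·3 bp from each side of the
   junction, translated in the 5′ partner's frame and truncated at the
   first stop. Fusions from two mitochondrial or two immunoglobulin genes,
   same-chromosome pairs within 500 kb (readthroughs) and 5′-lincRNA
   partners are filtered out.
3. **Binding.** Every length-n window covering a mutant residue is scored
   against the consensus alleles by a pluggable percentile-rank predictor
   (consensus = median of per-method percentiles; lower = stronger). Calls
   in the top 5 % are kept, and only then is the wildtype counterpart
   peptide assayed for comparison. A deterministic seeded mock predictor
   ships for testing; real predictors plug in behind the same interface.
4. **Ranking.** Per IAR the features npa (accepted calls), nph (calls with
   percentile ≤ 1.0), nmhc (distinct alleles hit), TPM, nwt (mutant binds
   better than wildtype) and ovlp (nested 9-in-10-mer pairs on one allele,
   class I only) are scored as within-run empirical quantiles in [0, 1].
   With weights `W_x` (defaults: class I `W_ovlp = 0.68`, `W_nmhc = 0.32`;
   class II five covariates at 0.2) each candidate gets
   `boost = Σ W_x · boost_x`, and for three iterations

   ```
   new_rank = old_rank · (1 − boost)
   ```

   with re-sorting between iterations, yielding the final positions.

## Worked example

The package ships a seeded synthetic-study generator (toy genome, GTF,
five caller VCFs, indel VCF, fusion BEDPE, expression, HLA lists, phasing
RNA reads) with every planted event recorded in a truth table:

```console
$ neopept make-fixtures --seed 17 --out demo
fixture written to demo (94 truth rows)
$ neopept run --config demo/config.yaml --truth demo/truth.tsv
12 consensus variants, 12 IARs, 167 class I / 77 class II calls -> demo/out
truth check: 94 checks passed
```

The head of the class I report (`demo/out/ranked_I.tsv`):

```
final_position  iar_id               source_type  peptide_10           npa  nph  nmhc  tpm    ovlp  boost
1               iar_0002_GENEA       snv          RFVQGKDWGVKKFIRRDFL  67   66   6     120.5  60    0.954
2               iar_0011_FUS5_FUS3   fusion       DNSKMALNSEALSVVSED   54   54   6     80.0   48    0.857
3               iar_0012_FUS5_FUS3S  fusion       DNSKMALNSELS         36   36   6     60.0   30    0.760
```

Row 1 is the planted missense F133V: the 10-mer context is the 19-residue
window `RFVQGKDWG·V·KKFIRRDFL` around the mutant valine, hit by 67
accepted peptide:allele calls across all 6 class I alleles. Rows 2–3 are
fusion junction contexts of 2·(n−1) = 18 residues, the second truncated
to `…ELS` by a stop codon three codons past the junction. The boost column
is the weighted quantile score that moved each region up the list.

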
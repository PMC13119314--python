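# Methods

This note documents the statistical model behind `rlpkit`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer should know about.

## Editing-event model

A deaminase reporter converts bases on RNAs proximal to its anchored
compartment: TadA produces A-to-I (sequenced as A>G), APOBEC1 C-to-U
(C>T). The caller compares per-site base counts from an induced sample
against uninduced controls and keeps a site as an event only if all four
criteria hold:

1. **Control absence** — every control covering the site has at most
   `control_max_alt` (default 0) reads of the chemistry's alt base. The
   default is the strictest reading of "absent"; it is configurable
   because real controls carry sequencing noise. A site covered by no
   control is rejected by default (`missing_control_policy`), since its
   background is unknown.
2. **Single SNV type** — the chemistry's alt base carries at least
   `purity_min_fraction` (0.9) of the non-reference reads, and no other
   alt base exceeds `max_secondary_alt` (2) reads. Purity is a fraction
   plus an absolute cap rather than "exactly one alt base observed"
   because the literal rule would be depth-dependent. The cap is a
   standalone parameter (not tied to `min_alt`) so that tightening
   `min_alt` can only shrink the event set — a monotonicity property the
   test suite enforces.
3. **Support** — at least `min_alt` (3) edited reads.
4. **Per-transcript floor** — events are retained only on transcripts
   with at least `min_events_per_transcript` (3) events whose editing
   ratio exceeds `min_event_ratio` (0.01). The ratio threshold is applied
   per event (each counted event must individually exceed 0.01); the
   alternative transcript-aggregate reading was rejected because the
   per-event form matches the single-cell thresholds (a gene is "edited"
   in a cell at ≥3 events) and makes the floor well-defined for
   unbalanced depths.

Conversions are reported in transcript orientation: genomic T>C on a
minus-strand gene is an A>G event. Strand and gene assignment use one
designated transcript per gene — the longest, a convention chosen because
per-gene positional quantities need a single reference isoform;
ties break lexicographically for determinism.

Upstream alignment-level filters (base quality, INDEL/read-end
proximity) are assumed already applied to the site-count table; the
caller's contract starts at base counts.

## Quantification

- `edit_count` (E_g,s) sums the supporting reads of a gene's events —
  multiple edits on one read count individually.
- `ECPM_g,s = E_g,s / Σ_i E_i,s × 1e6`. Deliberately not
  length-normalized: editing by a poly(A)-anchored enzyme concentrates
  near the 3′ end, so occurrences do not scale with transcript length
  (the suite checks |Spearman ρ| < 0.1 against length on
  length-independent synthetic data).
- `EPM` counts **distinct sites** per million mapped reads, while ECPM
  counts **occurrences** — the two sample-level vs gene-level activity
  measures are intentionally different numerators; both are exposed.
- Metagene density is a histogram of transcript-space distance from the
  poly(A) site (0 = 3′ terminal base), normalized to unit mass inside
  the window (default 1,000 nt, 50 nt bins); farther events are counted
  separately rather than silently dropped.
- Expression-binned summaries use 10 equal-width bins spanning the
  observed log2-expression range after dropping genes at or below the
  expression floor (default linear expression ≤ 1). Bins are left-closed,
  the last bin closed on both sides; SE = sd/√n with the n−1 denominator;
  a singleton bin reports SE 0.

## Localization index and temporal clustering

`LI_g = log2((E_comp/R_comp) / (E_cyt/R_cyt))`. Genes with zero reads in
either sample are always excluded; genes with zero edits are excluded by
default or, in pseudocount mode, given +0.5 edit counts (the pseudocount
mode exists for exploratory use; the default mirrors computing LI only on
detected genes). LI is antisymmetric under swapping the samples.

Time courses of LI are row z-scored (mean 0, SD 1, n−1 denominator;
constant rows are excluded and reported) and clustered by average-linkage
(UPGMA) agglomeration under correlation distance d = 1 − Pearson r.
Pearson rather than rank correlation is the default because z-scored
trajectories are already on a common scale; the metric is configurable.
The number of flat clusters k is user-supplied. Clustering is delegated
to scipy's hierarchy module; its deterministic merge ordering provides
reproducible dendrograms, and heights are non-decreasing (ultrametric).
Newick export encodes branch lengths as merge-height differences.

## Single-cell statistics

QC proceeds in three ordered steps: (1) gene retention (≥5 supporting
reads in ≥2 cells, when a read-support matrix is available — TPM rows are
renormalized afterwards); (2) a detected-genes floor per cell (default
9,000; "detected" = TPM > 0); (3) editing-activity outlier removal with
quartiles by linear interpolation (the type-7 convention — recorded
because fence positions depend on it): NES mode removes cells outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] on edited-gene count and, when provided, on
per-cell editing ratio; ERM mode removes cells with fewer than 200 edited
genes or above Q3 + 3·IQR. Fences are inclusive — a cell exactly on a
fence is kept. Fewer than four cells at the fence step is an error
(quartiles unstable). "Edited gene" means ≥3 edits in that cell.

A gene's **detection rate** is the fraction of passing cells with ≥3 of
its edits. Rates are binned into [0,0.1), …, [0.9,1.0] (top closed; a
rate exactly at a boundary belongs to the upper bin); zero-rate genes are
excluded from the histogram and reported separately so that observed and
shuffled supports are comparable (the shuffle can only retain genes with
simulated signal).

The **shuffle null** asks whether detection heterogeneity exceeds what
expression alone explains: per shuffle and per cell, the cell's observed
edit total is redistributed over genes by a multinomial with
probabilities proportional to the cell's TPM row; genes with ≥3 simulated
edits in ≥1 cell are retained; rates are recomputed and binned. Three
shuffles (the analysis's convention; configurable upward) give a per-bin
mean and SD. The chi-square goodness-of-fit statistic Σ(O−E)²/E compares
observed bin counts to the shuffle mean **rescaled to the observed
total** (so only shape is tested); bins with expected count <5 are merged
rightward (the last bin leftward) before testing, df = bins used − 1.
Rescaling and merging are standard validity conditions; both are
recorded in the result object.

Measured at the generator defaults (50 cells × 300 genes, 3 shuffles),
the test's empirical type-I error at α = 0.05 is ~2–6% over 200 null
datasets, and power against the planted subset-restricted alternative
(20% of genes, 10% of cells, 5× weight) is ≥98% — both recomputed by
`scripts/acceptance.py` and the acceptance tests.

## Detained-intron ratio

For intron k of the designated transcript, per cell:
`ratio = mean_cov(intron_k) / ((mean_cov(exon_k) + mean_cov(exon_k+1))/2)`,
with exon/intron indices in transcript order. Cells with both flanking
means zero are undefined and reported, not imputed. The ratio is
invariant to per-cell depth scaling, so no cross-cell normalization is
applied — an assumption that holds as long as coverage bias within a gene
is depth-independent. Group contrasts use the two-sided Mann–Whitney U
(exact at small tie-free samples, matching full permutation enumeration
at n = 5+5) plus the fold change of group medians; when a median is zero
a pseudocount (default 0.01) is added to both medians and the result is
flagged.

## Sequence context

Contexts are (2·flank+1)-mers (default flank 10) around each event,
reverse-complemented for minus-strand events so matrices read 5′→3′ in
transcript orientation, with position 0 the edited base and upstream
positions negative — the AC preference of APOBEC1 is A at −1, C at 0; the
TA preference of TadA is T at −1, A at 0. Events too close to a contig
end are excluded and reported. Frequency columns sum to 1; enrichment is
log2(freq/background) against a user-supplied base-composition table
(default uniform; no organism-specific background ships with the
package), with −∞ possible at zero frequencies. Adenosine content is the
A fraction over unambiguous bases (N excluded from the denominator).

## Synthetic generators

One top-level seed fans out to named substreams (CRC-keyed
`SeedSequence` spawn keys), so each generator is byte-deterministic and
adding one never perturbs another. `SimulationTruth` holds every
parameter and serializes to JSON beside generated outputs.

- **Transcriptome**: 1–5 exons per gene (150–400 nt exons, 50–200 nt
  introns), one gene per contig, both strands, exonic sequence carrying
  the chemistry's dinucleotide at a controlled density (5% default).
- **Bulk**: per-gene depth lognormal around 100; compartment members
  (30%) carry edits at motif sites whose transcript-space distance to the
  poly(A) site lies in [50, 250) — the positional law mirroring a
  poly(A)-anchored enzyme — with per-read editing probability 0.1;
  controls carry only a flat per-site error rate (0 by default);
  pure-reference background sites are included so the caller sees
  negatives.
- **Cells**: TPM lognormal around gene means, renormalized to 10⁶ per
  cell; core genes edited in a 95%-probability cell subset and rare genes
  in a 5% subset (Poisson mean 6, floored at 3 so membership implies
  detection); all remaining genes receive the cell's null edit total
  (Poisson mean 1,500) by a TPM-proportional multinomial — exactly the
  shuffle null's law, which is what makes the type-I property testable.
  The 1,500 default reflects that a passing cell in this assay carries
  hundreds of edited genes (the ERM QC floor alone implies ≥600 edits),
  scaled to the 300-gene default transcriptome. An optional
  heterogeneous mode restricts a gene fraction's editing to a small cell
  subset at elevated weight, conserving per-cell totals.
- **Time course**: rising (linear), peaked (Gaussian bump at the middle
  timepoint) and flat LI shapes with additive Gaussian noise (SD 0.3) on
  the log2 scale, converted to edit/read profiles at 10⁵ reads so
  integer rounding is negligible.
- **Intron coverage**: exon coverages lognormal around 50×, intron
  coverage = flanking mean × phase retention × lognormal noise; with
  noise 0 the ratio is exactly the retention parameter.

What the generators do **not** emulate: alignment artifacts, positional
coverage bias within transcripts, UMI/duplication structure, SNP
contamination, overlapping genes, alternative isoforms, doublets, or
batch effects. Passing tests therefore demonstrate correctness of the
statistics under the stated sampling models, not robustness to upstream
artifacts — those are the responsibility of the alignment/filtering
steps that produce the package's inputs.

## Problem sizes and numerical notes

Default study conditions: 300 genes, 100 cells, 7 timepoints; the
statistical error-rate properties use 50 cells × 300 genes per dataset,
200 null and 100 alternative replicates; recovery properties use 200
genes × 7 timepoints (20 seeds), 10,000 events for the positional law,
and 1,000+ events for motif recovery. Everything runs in seconds to a
few minutes on one CPU.

Ties and degenerate inputs: UPGMA relies on scipy's deterministic merge
order; quantile fences are inclusive; empty samples (no edits), constant
z-score rows, zero-depth sites, zero-TPM cells, and fewer than four
cells at the IQR step are explicit errors or reported exclusions rather
than silent NaNs.
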
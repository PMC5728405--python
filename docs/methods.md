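# Methods

`splicexport` quantifies the cellular phenotypes of defective mRNA splicing
and nuclear export: nuclear retention of poly(A) RNA measured by FISH,
DNA-repair foci that accumulate when damage-response transcripts fail to be
expressed, fluorescent splicing-reporter ratios, qPCR-based splicing and
export indices, the differential-expression set arithmetic that defines
knockdown target-gene lists, and 3'-UTR motif enrichment in those targets.
Every stage is exercised on synthetic data with recorded ground truth, so
the package's claims are about measurement correctness, not about any
particular biological dataset.

## Image model and the N/C ratio

Nuclei are segmented from the DAPI channel by Gaussian smoothing
(sigma = 1 px), a global Otsu threshold, hole filling and a minimum-area
filter (default 50 px); touching nuclei can optionally be split by a
distance-transform watershed seeded at smoothed distance maxima. The
algorithm is deliberately the plainest reproducible pipeline for
high-contrast DAPI fields; it is a declared choice, since this kind of
measurement is conventionally done with ad hoc plugins whose parameters are
rarely published.

The nuclear measurement region subtracts a 2-px shell from the mask
perimeter: morphological erosion with the 3x3-square (Chebyshev)
structuring element applied `erosion_px = 2` times, which matches ImageJ's
default binary-erosion semantics and keeps square-fixture arithmetic exact
(a 20x20 square erodes to 16x16 = 256 px). The cytoplasmic region is a ring
of width `ring_width_px = 30` starting `ring_gap_px = 2` outside the
nucleus boundary: pixels whose Euclidean distance to the nucleus pixel set
lies in (gap, gap + width], excluding every nucleus. Where rings of
neighbouring cells meet, each pixel belongs to its nearest nucleus,
competing over the whole neighbourhood including the gap zone (so a pixel
hugging one nucleus is never claimed by a farther nucleus's ring); exact
distance ties go to the lowest label, a deterministic convention the
brute-force oracle reproduces. Whether the original convention starts the
ring at the original or at the shrunk nucleus boundary is ambiguous;
gap-outside-the-original-boundary is this package's declared reading, and
both the gap and the width are configurable.

Per cell, the N/C ratio is the mean signal intensity over the eroded
nuclear mask divided by the mean over the ring. No background subtraction
is applied before the ratio (an optional flag exists); the ratio is
invariant under any positive rescaling of the signal channel. Cells whose
ideal ring band would leave the image are flagged `border` and excluded
from condition means by default, as are cells with an empty ring, a
non-positive ring mean, or a nucleus that vanished under erosion.

## Foci scoring

Foci are isolated with a white top-hat (disk footprint of radius twice the
expected focus radius, default 2 px, so 4 px), thresholded per nucleus at
median + 5 x MAD of the top-hat values inside the nucleus interior (the
nucleus eroded by the top-hat radius — the opening leaves artefacts in a
boundary band, which the interior restriction ignores), and counted as
connected components of at least 2 px. All of these are parameters; none is
claimed to match the original scoring software, and the detector is
validated only against synthetic ground truth. A cell is scored
focus-positive when its count is **at least** `min_foci = 5`: the methods
wording "more than 5" conflicts with the figure convention ">=5" used in
every quantified panel, and the figure convention wins (configurable).

## Reporter and DR-GFP readouts

The splicing reporter is scored as the per-cell ratio of mean numerator
(GFP) to mean denominator (RFP) intensity over the cell mask; cells whose
denominator mean falls below `min_denominator` are treated as untransfected
and dropped. The ratio is equivariant under per-channel positive rescaling.
The homologous-recombination readout is simply the mean of per-nucleus mean
GFP intensities with its SEM.

## Differential filtering and set arithmetic

The expression stage consumes already-normalized replicate tables (tidy
CSV: gene, condition, replicate, compartment, value). Per gene, the
fold-change is the ratio of cytoplasmic replicate means (condition/control,
linear scale) and the p-value a two-sided t-test on log2 values. The
default is the pooled-variance Student test. Welch's test is available, but
at n = 3 replicates its Satterthwaite degrees of freedom collapse toward 2
whenever the two sample variances diverge, which inflates far-tail p-values
enough to destroy recovery of even strong planted effects (Monte Carlo at
the default conditions: probability of passing the BH cutoff 0.76 under
Welch vs 0.9999 under Student); the pooled test also matches the
two-tailed Student convention used for every other comparison in this kind
of analysis. Genes with (numerically) zero variance in both groups get
p = 1 when means are equal and p = 0 flagged `degenerate` otherwise.

Benjamini-Hochberg adjustment is implemented directly as the step-up
cumulative minimum (order-preserving, capped at 1); tests cross-check it
against both a definition-level oracle and `statsmodels`. "Down-regulated
by more than 1.5-fold" means fold-change strictly below 1/1.5; the
significance rule is FDR-adjusted p < 0.01 for single-knockdown lists, with
raw p < 0.05 available as a switch because published double-knockdown
counts are quoted at that rule and the exact combination is ambiguous.
Overlap reports give |A|, |B|, |A∩B|, |A∪B| and the intersection as a
percentage of the union, rounded half-up to one decimal (the printed
13.6% = 191/1407 is consistent with the union denominator — an inference,
documented as such); `fraction_of_universe` is the same rounding of
100·|S|/N.

## Motif scanning

The scanner is a deliberately simple, fully specified replacement for
EM/PWM motif discovery (which is a non-goal): exhaustive k-mer counting
over widths 8–20. Each k-mer present in at least `min_support = 5`
sequences is scored by a one-sided binomial tail on the number of sequences
containing it, against an order-0 background (pseudocount 1 per base); the
per-sequence occurrence probability uses the independence approximation
1 − (1 − p_kmer)^(L−k+1), whose error against exact enumeration on short
sequences is tested (it is largest for self-overlapping k-mers). The tail
is computed by log-sum-exp so extreme enrichment does not underflow.
Significance is Bonferroni-corrected across **every distinct k-mer
enumerated** over all widths, not only those above the support floor:
correcting only over high-support survivors is a selection-biased universe
that produces spurious rejections on null data. Hits are ranked by score
with lexicographic tie-break; a hit contained in a longer hit is annotated
`nested_in`. Reverse complements are never collapsed — the input is
single-stranded mRNA. Recovery of a planted consensus is the acceptance
surface; no claim is made of matching any EM-based tool's motif boundaries.

## qPCR quantification

Relative quantification is the textbook in-run standard-curve method: per
primer, least-squares Cq ~ log10(concentration), efficiency
10^(−1/slope) (sanity band (1, 2.2]), unknowns read off as
10^((Cq − intercept)/slope). Technical replicates are averaged on the
concentration scale after quantification (a declared rule; Cq-scale
averaging is not offered because the pipeline's indices are ratios of
concentrations). All derived indices — reference-gene (ACTB)
normalization, pre-/post-spliced levels from exon–intron vs exon–exon
primers, N/C ratios from compartment-matched normalized values — are
invariant under a common rescaling of all true concentrations. QC:
fractionation purity fails when cytoplasmic/nuclear MALAT1 exceeds
`malat1_max_ratio = 0.1` (no published threshold exists; 0.1 is a
conservative default), and a primer fails the RT-minus check when any of
its RT-minus wells amplified (finite Cq instead of the NaN
no-amplification sentinel).

## CDS variant arithmetic

1-based CDS coordinates with the A of the ATG as position 1: codon index
⌊(pos−1)/3⌋+1, position-in-codon ((pos−1) mod 3)+1. Consequences come from
the standard nuclear genetic code. `truncated_length` for a nonsense
variant is codon_index − 1: the stop replaces the affected residue, so a
stop at codon 101 retains 100 residues. Descriptions of such variants as
producing "a 101 aa protein" count the mutated codon itself; the package
reports the stop-replaces-residue convention and does not reproduce that
off-by-one.

## Condition statistics

Mean ± SEM (sd with n−1 denominator over √n; SEM is NaN, not 0, for a
single value), two-tailed two-sample t-tests (Student pooled by default,
Welch optional), star annotation at the tiers * p < 0.05, ** p < 0.005,
*** p < 0.0005 (the unusual 0.005 middle tier is the majority convention
in this assay family's figure legends; one panel's ** p < 0.001 variant is
why the tiers are configurable). Clonogenic surviving fraction is
(colonies/seeded)/plating-efficiency with the untreated point of each
knockdown defining its own plating efficiency, making its surviving
fraction exactly 1. No multiple-testing correction is applied across assay
panels.

## Synthetic data: what it emulates and what it does not

The generators render what each stage needs with analytically known ground
truth:

* **FISH fields** — jittered-ellipse nuclei (default radius 15 ± 20% px,
  50 cells on 768x768) with a hard-edged signal channel:
  `cyto_level x true_nc_ratio` on nuclear pixels, `cyto_level` (400) on a
  cytoplasmic annulus extending 40 px from the nucleus, background 100
  elsewhere, so the noiseless mask-level N/C ratio equals the planted
  value exactly. The DAPI channel gets Gaussian-smoothed edges for
  realistic segmentation. Cell placement enforces disjoint nuclei with a
  clear gap and keeps whole cells away from the border.
* **Foci fields** — hard disks (radius 2 px, amplitude 2000 over a
  pan-nuclear base of 300) planted at recorded positions, pairwise
  disjoint and kept 7 px inside the nucleus so detection margins never
  clip them; nucleus radius defaults to 20 px so up to ~10 foci fit.
* **Reporter fields** — whole-cell disks with per-cell planted
  numerator/denominator ratios, exact on masks at zero noise.
* **Expression tables** — per-gene log-normal baselines (log2 mean 7,
  sd 1.5), multiplicative log-normal replicate noise with default
  sd 0.05 on the log2 scale (technical-replicate-level variability of
  normalized arrays — the planted-recovery conditions are explicitly
  low-noise, and a power analysis at n = 3 and 2.5-fold effects puts the
  Student-test pass probability at the BH cutoff above 0.999 at this sd),
  planted genes multiplied by their fold-change in the cytoplasmic
  fraction of their condition only.
* **UTR sets** — i.i.d. background nucleotides (default uniform, 200
  sequences of 300 nt) with one motif copy overwritten at a recorded
  position in a chosen fraction of sequences.
* **Cq tables** — Cq = intercept − log10(conc)/log10(efficiency) + N(0,
  sd), a 10-fold five-point standard series and one RT-minus well per
  primer, optional planted contamination.

Noise is additive Gaussian on a constant background; Poisson shot noise,
point-spread functions, uneven illumination, 3-D structure, cell-shape
realism and probe-specific effects are deliberately not modelled. Passing
tests therefore demonstrate that the measurement code recovers known
parameters under the declared geometry and noise model — they do not
validate segmentation or spot detection on real micrographs, where the
original acquisition parameters are unknown anyway.

Determinism: every generator takes a seed and produces bit-identical
output for an identical spec + seed; seeded streams are part of the public
interface. Images are float64 in memory and quantized to 16-bit on write,
so TIFF round-trips are lossless exactly when intensities are integral
(noiseless defaults); float32 output is available where fractional
intensities matter.

## Numerical choices and problem sizes

Ring/erosion geometry is computed per label on padded bounding-box crops
(exact, since the pad covers the band) and validated pixel-for-pixel
against per-pixel brute-force oracles on fixtures up to 64x64. The test
and analysis scales — 20 seeded FISH fields of ~50 cells, 10 foci fields,
20 expression simulations of 5100 genes at n = 3, 10 + 10 motif scans of
200x300-nt sets — were chosen to estimate recovery rates stably while
keeping the full suite to a few minutes on one CPU.

## Known limitations

* Absolute agreement with any published figure values from real images is
  not claimable: the original plugin's segmentation parameters are
  unknown, and no raw data are deposited.
* The motif scanner reports exact k-mers only; degenerate (PWM) motifs
  will surface as a family of related k-mer hits rather than one
  consensus with ambiguity codes.
* The qPCR module consumes Cq values; amplification-curve processing,
  melt curves and the ΔΔCq method are out of scope.
* The expression stage assumes pre-normalized tables; array
  normalization, probe mapping and moderated-variance statistics are out
  of scope.
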
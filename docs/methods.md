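# Methods

`loopgrammar` packages the sequence- and contact-level computations used to
characterize the motif grammar of chromatin loops — which transcription-factor
motifs sit at the two anchors of a Hi-C loop, how they are oriented, how a
cofactor motif (MAZ's GGGAGGG) is spaced around CTCF, and how loop and TAD
contact activity changes between conditions. Because these analyses are
normally run on deposited sequencing data, the package ships a seeded
ground-truth generator that emulates the statistical structure the methods
assume, so every computation can be validated by recovery of planted truth.

## Motif scanning

A motif is a position weight matrix (PWM): per-position probabilities over
A/C/G/T plus a zero-order background. A window w of length K scores

    S(w) = sum_k log2( p_k(w_k) / b(w_k) )   [bits]

on the forward strand; the '−' strand scores the reverse complement. Both
strands are scanned at every offset, and windows containing N are skipped.

**Exact p-values.** Significance of a score is the probability that a random
background word scores at least as high. Scores are discretized to a grid
(default 10⁻³ bits, coarsened so the table never exceeds 10⁵ cells) and the
exact distribution of the discretized score is built by dynamic-programming
convolution over motif positions — the same construction used by FIMO-class
scanners. Because a hit's p-value is looked up from its own discretized score,
DP p-values agree with exhaustive 4^K enumeration to floating-point error
(tested to 1e-12 for K ≤ 6). The default reporting cutoff is p ≤ 10⁻³.

For speed, genome-scale scans pre-filter candidate windows on the float score
with a K/2-grid-cell rounding margin and rescore only candidates on the
integer grid; this is exact (no candidate below the margin can reach the
integer threshold) and is verified against a naive per-window oracle.

## Anchor annotation and orientation classes

Loops are cis anchor pairs; the 5′ anchor is by convention the
lower-coordinate anchor. To suppress spurious sequence matches, motif search
at an anchor is restricted to the intersection of the anchor with the
factor's ChIP peaks (the union of intersections when several peaks overlap
the anchor); per anchor and factor, the single highest-scoring contained hit
is kept (ties: lowest start, then '+').

A loop with hits on both anchors is classified from the two strands:
(+, −) convergent, (−, +) divergent, (+, +)/(−, −) tandem; loops with a
missing hit are unclassified and excluded from proportion denominators.
Proportions are reported per group over classified loops.

An optional binary occupancy filter keeps only loops whose ChIP signal at
both anchors reaches a per-factor cutoff, and `relative_orientation` reports
whether the MAZ motif lies loop-ward ("inside") of the CTCF motif on an
anchor. The positional reading (midpoint comparison; ties outside) is the
default; a strand-based reading (MAZ motif pointing loop-ward) is available
via `mode="strand"`, since either interpretation of "inside" is defensible.

## CTCF–MAZ spacing

For each primary (CTCF) site — deduplicated by overlap, and in practice
restricted to peak-contained hits so windows are centered on binding
regions — a 500-bp window centered on the motif midpoint is scanned with the
secondary (MAZ) PWM, and the best hit's signed center-to-center offset is
recorded, oriented by the primary strand (positive = downstream of a '+'
primary). Offsets are binned (default 5 bp) and each bin is tested for
enrichment with a one-sided binomial test against a uniform-placement null,
BH-corrected across bins.

The null accounts for two geometric constraints: the secondary midpoint can
only lie in [−w/2 + K₂/2, w/2 − K₂/2], and the central
±(K₁ + K₂)/2 region is occupied by the primary motif itself, so a
non-overlapping secondary instance cannot sit there. Both the observed
offsets and the per-bin null probabilities exclude that central footprint
(SpaMo's convention). Without the exclusion the per-bin null mass is
underestimated by ~5% and the family test becomes slightly anticonservative.

## Contact matrices

Matrices are symmetric per-chromosome bin-count grids (20-kb default bins;
read pairs closer than 25 kb are dropped at binning).

**Balancing.** Iterative correction (ICE) removes multiplicative per-bin
visibility biases: all-zero bins plus the lowest-coverage 2% of nonzero bins
are masked, then row-sum bias updates repeat until the maximum relative
row-sum deviation is below 10⁻⁶ (error on non-convergence). The balanced
layer is scaled to unit row sums off the mask, which makes it directly
comparable to an alternating row/column (Sinkhorn) normalization oracle.
Balancing is idempotent: re-balancing shifts biases by less than the
tolerance.

**Expected profile and O/E.** The expected contact at bin distance d is the
mean over unmasked pixels of that diagonal (optionally made non-increasing).
Observed/expected (O/E) grids underlie APA, intra-TAD activity and the
simple loop caller.

**APA and P2LL.** Aggregate peak analysis averages the (2N+1)² O/E window
(N = 10 flank bins) centered on each loop's anchor-midpoint pixel at 5-kb
resolution, skipping loops whose window crosses the diagonal (distance
< (2N+2)·resolution) or the matrix edge; the matrix must already be at the
requested resolution (no silent re-binning). P2LL divides the central pixel
by the mean of a ⌊(2N+1)/3⌋-sized corner block. With rows indexed by the
upstream anchor and drawn top-to-bottom, the corner nearest the diagonal is
the displayed lower-left block (high row, low column indices); that is the
default background corner, and the choice is configurable. A constant
aggregate gives exactly 1; a loop-free matrix with random loop positions
gives ≈1.

**Boundary scores and TADs.** The per-bin insulation "ratio" score divides
the mean of contacts crossing the bin (pairs spanning i within a ±W window;
W = window/bin_size, windows 250 kb / 500 kb / 1 Mb, default 500 kb) by the
mean of the two flanking intra-window triangles, so boundaries score *low*.
Bins without full flanking windows are undefined. Boundaries are local
minima of the defined track with z ≤ −1, where the dispersion used for z is
floored at 5% of the track mean — this makes the caller silent on flat or
pure-decay matrices, whose fluctuations are far below a real insulation dip
(planted 2.5× TADs dip ~40%, Poisson noise on the track is ~1–2%). At the
masked chromosome ends the minimum test is one-sided against the available
neighbor. TADs are the intervals between consecutive boundaries; a boundary
closer to the chromosome end than half a window has no defined score and
cannot be recovered.

**Intra-TAD activity.** The magnitude of intra-TAD activity is defined here
as the mean O/E over all intra-TAD pixels (TADs under 3 bins are flagged).
This is a deliberately simple definition — comparisons between conditions
are relative, and a matrix equal to its expectation scores exactly 1.

**Differential activity.** Loop (or TAD) counts per replicate are
CPM-normalized by the replicate's total mapped pairs (falling back to
feature-table column sums when totals are unavailable — note the fallback
biases log-fold-changes toward zero when a condition loses signal globally).
The reported log2 fold change compares mean CPMs with a +0.5 CPM prior. The
p-value is the two-sided conditional Poisson rate test (a binomial test of
the pooled condition split against the library-size split), BH-corrected
across features. Significance requires FDR ≤ 0.005 and |log2FC| ≥ 1.5 for
loops (TAD comparisons conventionally use FDR ≤ 0.05 with no fold-change
cutoff). Swapping condition labels negates every log2FC and preserves
p-values exactly.

**Simple loop caller.** For synthetic end-to-end runs only, raw pixels are
tested one-sided Poisson against the raw distance expectation, BH-corrected;
significant pixels merge into 8-connected clusters whose maximum-count pixel
is reported. It is a stand-in that closes the pipeline on generated data,
not a production caller.

## Synthetic scenarios

One seeded generator (NumPy PCG64) drives each scenario with a fixed draw
order — TAD tiling, loops, perturbed-loop choice, genome background, motif
planting, peaks, then matrices (WT replicates before KO) — so a scenario is
bit-reproducible from its seed. Defaults are chosen once as realistic study
conditions:

| parameter | default | rationale |
|---|---|---|
| chromosome | 30 Mb single test chromosome | large enough for 300 non-colliding 20-kb anchors |
| GC fraction | 0.42 | mammalian-like |
| loops | n = 300, classes (0.60, 0.30, 0.10) conv/tand/div | convergence-dominated anchor grammar |
| loop distances | 100 kb + Exp(400 kb), capped 3 Mb | median span of a few hundred kb; ~99% below 2 Mb |
| CTCF motif | 19-bp synthetic consensus PWM (p = 0.94) | CTCF-class length/information |
| MAZ motif | GGGAGGG PWM (p = 0.97) | GC-box class |
| MAZ offset | uniform 70–140 bp from CTCF, loop-ward of its strand | observed cofactor spacing range |
| bins / decay | 20 kb, (d+1)^−1 | standard Hi-C binning and decay |
| TADs | 0.4–1.2 Mb tiling, 2.5× intra enrichment | typical domain sizes/strength |
| loop pixels | 3.0× enrichment, 1-bin halo at half strength | corner-peak morphology |
| depth | 10⁷ cis pairs per replicate, 2 replicates | loop-resolution (deep) Hi-C on a 30-Mb chromosome |
| KO | 30% of loops attenuated to 0.25× | global loop weakening after cofactor loss |

CTCF instances are planted as consensus words at anchor-bin centers with
strands dictated by the loop's class; MAZ instances at the configured signed
offset (rejection-resampled on overlap, which exactly excludes the central
footprint region); peaks are 200-bp intervals centered on instances with
log-normal signal and optional motif-free decoys. Contact expectations are
decay × TAD block × loop corner-peak, scaled so the WT upper-triangle total
equals the configured depth, and Poisson-sampled per replicate; the KO grid
keeps the same per-pixel scale with perturbed loop factors multiplied by the
attenuation, so the planted KO/WT expected ratio at a perturbed pixel is
exactly the attenuation factor.

Presets: `maz_ko_like` (the full knockout-like scenario above), `null` (no
loops, no TADs), `spacing_only` (500 CTCF sites, MAZ fixed at +85 bp for 70%
of sites), `apa_like` (200 loops, 3.0×, 5-kb bins, no TADs), `tad_like`
(TADs only on a 10-Mb chromosome).

**What the generator does not emulate** — and hence what passing recovery
tests do not establish about real data: read-level artifacts and mappability
(planted motifs are exact consensus words, so best-hit selection at anchors
is easier than with degenerate real motifs), fragment-level Hi-C biases
(bias vectors are flat, so ICE is exercised analytically rather than by
realistic bias removal), overdispersion beyond Poisson between replicates,
compartments, trans contacts, nested/overlapping TADs, and peaks that drift
off their motif. Recovery rates on these scenarios are upper bounds on what
the same procedures achieve on sequencing data.

## Problem sizes and determinism

The shipped tests and the acceptance script run everything at desk scale
chosen as the package's own validation conditions: 30-Mb (knockout-like) and
10-Mb (APA/TAD) chromosomes, 200–300 loops, 500 spacing sites, 500×500
balancing instances, 20 seeded null-calibration runs. All randomness flows
from explicit seeds; the CLI writes deterministic tables plus a manifest
(version, parameters, input checksums), and running the full pipeline twice
with one seed produces byte-identical outputs.

## Known limitations

* The insulation-caller's 5%-of-mean dispersion floor is a heuristic scale
  separating Poisson track noise from domain-strength dips; very weak
  (<~10%) boundaries fall below it by design.
* The conditional Poisson rate test assumes counts are Poisson across
  replicates; real Hi-C replicates are overdispersed, for which a
  negative-binomial framework would be needed.
* Loop anchors are single bins and loop pixels are read out at the anchor
  pixel only; callers that integrate a neighborhood would need the halo
  handled explicitly.
* `simple_loop_call` ignores bin biases (raw counts vs raw expectation) and
  is calibrated only in the synthetic setting.
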
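# Methods

`gbsflank` implements the computational chain linking the single base
pairs that flank a glucocorticoid receptor binding sequence (GBS) to
transcriptional response strength, DNA shape, protein conformation and
binding affinity.  This note records the models, the defaults and why,
what the synthetic data do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Coordinate conventions

A GBS is a 15-bp core of two 6-bp inverted-repeat half-sites around a
3-bp spacer.  Positions are labelled relative to the spacer centre (0):
half-site 1 at −7..−2, spacer at −1..+1, half-site 2 at +2..+7, and the
*proximal flanks* at −8 and +8.  A match is classed `WW` when both flank
letters are weak base pairs (A or T), `SS` when both are strong (G or C),
`mixed` otherwise, and `edge` when the 17-letter window leaves the
sequence.  Minus-strand matches are reported in match orientation (window
and flanks reverse-complemented); the WW/SS classes are strand-invariant
because each class is closed under complementation.  Genomic intervals
are BED-style 0-based half-open throughout.

## Responder stratification and peak association

Only genes with adjusted p < alpha (default 0.05) enter the analysis.
Strong responders are the top `top_fraction` (default 0.2) of significant
genes ranked by log2 fold change, with **ceiling rounding** so that 20%
of 1,447 genes gives exactly 290; ties at the cut are broken by gene id
for determinism.  Weak responders are significant genes with
|log2FC| ≤ 0.72.  A gene qualifying for both groups by arithmetic
accident is assigned to strong only, keeping the groups disjoint.

A peak is associated with a gene when its midpoint, `floor((start+end)/2)`,
lies in the half-open window `[TSS − w/2, TSS + w/2)` with w = 40 kb by
default.  Midpoint containment (rather than interval overlap) avoids
widening the effective window by the peak length.  The TSS of a
minus-strand gene is the annotation's end coordinate.  Peak counts per
group are reported but not subsampled to parity: the reference
experimental counts (543 strong-associated vs 532 weak-associated peaks,
and 83 A/T vs 75 G/C GBSs) arose from threshold choices on specific
public data sets with an unstated TSS annotation, so they are documented
here for context and not used as quantitative targets.

## Motif engine

**PWM.**  Frequencies are regularised as
`(count + pseudocount·bg) / (n + pseudocount)`; scores are log2
odds against a zero-order background; per-column information content is
the relative entropy in bits.

**Exact score threshold.**  The null score distribution is computed by
column-wise dynamic programming over the background after discretising
column scores into bins of `resolution` bits (default 0.01).  The cutoff
returned for a target p-value is the smallest achievable score whose
upper-tail mass is ≤ p (default 1e−4, the conventional matrix-scan
setting).  Discretisation can merge scores that differ by less than one
bin; the returned cutoff is exact for the binned distribution, which is
the quantity the tests enumerate.  A p-value below the smallest
achievable tail returns max score + one bin with a warning.

**Scanning.**  Both strands are scanned and all overlapping matches kept
(the conservative superset; greedy masking would need an arbitrary
priority rule).  Windows containing non-ACGT letters score −∞ and never
match.

**Spaced-dyad discovery.**  A deliberately simplified stand-in for a full
peak-motifs suite: for every pair of 3-letter words at spacings 0..20,
occurrences are counted over both strands and scored with an upper-tail
binomial p-value (n = available positions, success probability = product
of zero-order background word probabilities), an e-value correcting for
the number of dyads tested, and `sig = −log10(e)`.  This recovers the
planted half-site/spacer geometry at desk scale; it makes no attempt to
reproduce any particular discovery tool's output.

**Flank enrichment.**  Differential motif enrichment of this kind is
often scored with a normalized weight difference (NWD) statistic whose
definition lives in external software (RSAT matrix-quality); this
package instead defines the explicit match-rate statistic
`delta = (rate_strong_WW − rate_weak_WW) − (rate_strong_SS − rate_weak_SS)`
(matches per peak) with a label-permutation null and the add-one
correction `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`.  The statistic is
documented as non-identical to NWD; what is preserved is the question it
answers.  "A/T flanked" requires **both** flanks weak (and G/C both
strong); single-mismatch flanks are reported separately as `mixed`.

**Peak height by flank class.**  A peak joins the WW group when it has at
least one WW match and no SS match (symmetrically for SS); peaks with
both, or only mixed/edge matches, are excluded.  Medians are reported
with group sizes; an empty class yields NaN.

## DNA shape

Shape at position i is the table value of the pentamer centred on i, so
the two terminal positions at each end are undefined.  Minor groove width
(MGW, Å) and propeller twist (ProT, degrees) are base-pair-frame features
and treated as strand-symmetric: tables are keyed by the canonical
pentamer `min(word, revcomp(word))`.

The published pentamer query table is an external resource, so the
package ships a **synthetic surrogate** (`synthetic_shape_table`):
MGW = 3.4 + 2.4·GC + jitter(±0.2) Å and ProT = −13.5 + 9·GC + jitter(±1)°,
where GC is the pentamer's G/C fraction and the jitter is a fixed
multiplicative-hash term that decorrelates words of equal composition.
The ranges and the direction (A/T-rich → narrow groove, more negative
propeller twist) follow well-established B-DNA behaviour; the actual
values are synthetic.  A green shape test therefore establishes that the
machinery (alignment, lookup, masking, statistics) is correct and that
composition-driven signatures propagate — it does **not** validate any
particular biophysical prediction.  Any user table in
`pentamer<TAB>value` format can be loaded instead.

Aligned GBS windows are keyed on the spacer centre; `flank_pad ≥ 2`
(default 2) keeps enough context to evaluate pentamers at the ±8 flanks.
Rows whose padded window leaves the sequence are dropped and counted.
Per-position group comparison uses the two-sided Wilcoxon rank-sum test
with midranks: exact enumeration when the smaller group has ≤ 8
observations *and* the subset count is ≤ 2×10⁵ (an 8-vs-500 comparison
would otherwise enumerate billions of subsets), normal approximation with
tie correction beyond that.  Per-position A/T content is computed on the
same rows as the means (mask consistency).  All matches are used, not one
per peak; with one planted motif per synthetic peak the two conventions
coincide on the fixtures.

## NMR chemical shift perturbation

CSP between two states is `sqrt(ΔδH² + (γ·ΔδN)²)` in ppm with
γ = |γ(¹⁵N)/γ(¹H)| = 0.1014 by default.  Both this convention and a
variant with an overall 1/√2 factor circulate in the literature; the
factor is exposed as a config toggle and changes the cutoff and the CSPs
by the same scale, so the significant set is invariant.  The significance
cutoff is mean + k·sd (k = 1) over residues with a defined CSP; residues
present in only one list get NaN and are excluded from the cutoff
statistics.  When a residue shows several peaks in a state (split peaks,
a signature of multiple conformations) the CSP is the minimal pairwise
distance in the normalised shift space — the most conservative
assignment — with all pairwise distances reported and the residue
flagged.

Titration analysis normalises each proton's intensity series to its
first (lowest-ratio) point and summarises it by the span-normalised area
under the curve; a proton is an outlier when its summary deviates from
the cross-proton median by more than k MAD (k = 3).  With a homogeneous
null of only ~11 protons the MAD is small and borderline extras can cross
3 MAD; the analysis driver prints this caveat when it happens.

## Binding equilibrium

The single-site isotherm is `f = 1/(1 + Kd/[P])` with [P] free protein.
At the bench condition of 1.25 nM DNA against micromolar protein, total ≈
free protein; a depletion-corrected mode solves the quadratic mass
balance exactly for cases where that approximation fails.  Kd is fitted
by least squares in log(Kd) — positivity without constraints — with the
standard error from the Gauss–Newton curvature mapped back by the delta
method.  All-equal fractions are non-identifiable and return
`converged = False`.  Replicates are fitted separately and summarised as
mean ± sd, matching the three-independent-replicates convention of the
bench experiment; pooled fitting would weight replicates by point count
instead.

## Ensemble geometry

Superposition is the Kabsch closed form with reflections excluded;
collinear point sets are rejected because the rotation is ill-defined.
RMSF uses two rounds of iterative superposition to the running mean (the
usual fixed point is reached quickly; `n_iter=0` gives the raw
fluctuation formula for pre-aligned frames), then averages atom
fluctuations within residues.  The "median structure" of a trajectory
tail is interpreted as the **medoid** — the frame minimising summed
pairwise superposed RMSD over the trailing `tail_fraction` (default 0.5)
— because a coordinate-wise median is not a physically realisable
conformation; ties break to the lowest frame index.  The atom subset
(backbone vs heavy) is the caller's choice upstream; all supplied atoms
are used.

## Synthetic data: what it emulates, what it does not

The regulatory fixture reproduces the *statistical structure* the
analysis assumes: a pool of 1,447 significant genes (log2FC drawn
uniformly in (0, 7.86), guaranteeing distinct ranks; non-significant
genes Normal(0, 0.2)), 500 peaks per responder group on a 50-Mb
chromosome, one planted 15-bp core per peak at a uniform offset keeping
the ±8 window inside the peak, flank classes drawn with bias 0.9 toward
A/T (strong group) or G/C (weak group), peak heights Normal(100, 20)
identical across groups, and each group gene's TSS anchored within 20 kb
of its first peak.  Background sequence is iid uniform A/C/G/T — a
neutral null for the enrichment statistics, chosen because the base
composition of receptor-bound regions is not part of the stated problem.
Real data differ in every inessential respect: non-uniform genomic
composition, read-level noise, peak-calling artefacts, multiple motifs
per peak, correlated expression errors.  Green tests on these fixtures
establish correctness of the computations and recoverability of planted
effects at the stated sizes, not biological claims.  When peaks outnumber
group genes, only each gene's first peak is guaranteed inside its window;
the remainder associate opportunistically, which mirrors the many-peaks-
per-gene structure of the real data.

The empirical fold-change spectrum is denser near zero than the uniform
draw used here (688 of 1,447 genes sat below the 0.72 weak threshold);
uniform is kept as the stated fixture world because it guarantees
distinct ranks for the top-fraction cut, at the cost of a smaller weak
group (~9% of significant genes).

## Degenerate inputs and tolerances

Zero-probability background letters raise before any p-value is
computed; empty site sets, empty peak groups and disjoint peak lists
raise immediately.  Score discretisation defaults to 0.01 bits
(configurable); the DP distribution sums to 1 within 1e−9.  Kd fits
tighten `xtol`/`ftol` to 1e−14 so noise-free round-trips reach 1e−6
relative error from initial guesses up to 10³-fold off.  Permutation
p-values are never 0 by construction (add-one correction).

## Known limitations

* The flank-enrichment statistic is a documented stand-in, not NWD.
* The dyad search is fixed at monad length 3 and a binomial null; no
  Markov backgrounds, no motif clustering or collection matching.
* Shape features beyond MGW/ProT (roll, helix twist) are not implemented.
* No spectral processing or peak picking: the NMR layer starts from
  assigned peak lists.
* No cooperative/Hill binding models; one site, one Kd.
* No trajectory formats beyond plain multi-frame XYZ; running the
  simulations themselves is out of scope.
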
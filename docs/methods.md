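# Methods

This note documents the models implemented in `flavodiel`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## Profile recruitment

The recruiter is a **calibrated position-specific scoring model**, not a
full profile HMM. The family profile is used purely as a yes/no
recruitment filter at a fixed E-value threshold, so what matters is the
calibration of scores against a null, not the absolute bit scale of any
particular tool; a PSSM with affine gap penalties reproduces that role
with a fully specified scoring function.

* Columns of the seed alignment with ≥ 50% residues become match columns.
  Score of amino acid *a* in a column:
  `log2(((count_a + τ·bg_a) / (n_obs + τ)) / bg_a)` with pseudocount
  τ = 1 and background `bg` defaulting to the WAG equilibrium
  frequencies. These are standard choices; results are insensitive to τ
  at the recruitment threshold used.
* Local alignment (Smith–Waterman) over match columns with affine gaps,
  gap open 10 bits, extend 1 bit. Query insertions and deletions relative
  to the profile are both permitted; insertion→deletion transitions are
  not (the usual simplification).
* **E-value calibration**: scores of *n* ≥ 1000 i.i.d. background
  sequences (default 2000, length matched to the query median) are fitted
  with a Gumbel by maximum likelihood — the asymptotic law for optimal
  local alignment scores. E(*s*) = db_size · P(S > *s*); db_size defaults
  to the number of sequences searched and is stated in the output header.
  On 10,000 fresh null sequences the fitted tail keeps the false
  recruitment rate at *E* < 10⁻³ far below 1%.
* **Dereplication** is greedy centroid clustering in (length descending,
  id ascending) order; pairwise identity = matches / global-alignment
  columns, computed from an edit-distance alignment (edlib). This matches
  the common usearch-style semantics; note greedy clustering depends on
  the processing order, which is fixed for determinism.

## Phylogenetic placement

Likelihoods use WAG exchangeabilities and equilibrium frequencies with
discrete-gamma rate heterogeneity (4 equal-probability categories,
category rate = conditional bin mean, overall mean 1). The gamma shape
defaults to α = 1 and is configurable; since the reference tree is taken
as given rather than re-fit, per-dataset α estimation is out of scope.
An observed-frequency mode is available by flag.

Felsenstein pruning treats gaps as missing data (an all-gap column
contributes exactly 0 to the log-likelihood) and rescales partials per
node and site, so trees with hundreds of leaves stay in floating range.
Correctness anchors: the two-taxon closed form
log(π_x · [P(b₁+b₂)]ₓᵧ) averaged over categories, re-rooting invariance
of a reversible model, and Chapman–Kolmogorov for the transition
matrices.

**Placement** attaches the query at the **midpoint** of each edge and
optimizes only the pendant branch length by golden-section search on
[10⁻⁸, 2.0] (tolerance 10⁻⁶). Full EPA implementations also optimize the
attachment point; midpoint attachment is the standard fast heuristic, and
the residual error is absorbed by the LWR confidence filter. On 100
simulated queries over random ≤ 8-leaf trees the midpoint best edge
matches a dense (attachment × pendant) regraft grid oracle in ≥ 95% of
cases. The engine caches below-edge and above-edge conditional
likelihoods once per (tree, alignment), so one pendant evaluation costs a
single 20×20 matrix product per rate category.

LWRs are normalized over **all** tree edges (not a candidate subset) with
a numerically stable softmax of log-likelihoods; ties in the best edge
break to the smallest edge id. A query must map to ≥ 10 reference
columns. The kept/filter rule is: best-edge LWR > 0.8, the distal leaf
set of the best edge contains exactly one genus, and that genus's clade
is clade I or clade II. The filter uses the *single best* placement's
LWR; an accumulated-over-clade variant would be more permissive and is
deliberately not the default. Queries are expressed in reference-alignment
coordinates (insertions relative to the reference are dropped), produced
either upstream or by the package's own profile alignment traceback.

## Taxonomic normalization

The taxonomy is a plain TSV (taxid, parent, rank, name), so no external
database is needed. LCA is computed by the depth-aligned pairwise walk,
folded over the input set. Contigs whose LCA resolves **above** order
rank are excluded from order denominators (and logged): including them
under any one order would double-count mass, and spreading them would
invent information.

Normalization stages, in order: (1) reads per liter,
rpl = count × mean over 14 standards of (added copies / recovered reads)
/ liters, with zero-recovery standards excluded from the mean (a robust
median mode is available by flag; all standards zero is an error);
(2) sum over contigs to clade × genus; (3) divide by the order total of
the genus's order in the same sample — a zero denominator yields NA,
never 0 or ∞; (4) average replicates (NA-ignoring), then sum the two
size fractions (NA + x = x, NA + NA = NA), following the stage order
normalize → average → sum. Scaling all counts of a sample by a constant
scales rpl but cancels exactly in the order fractions. TPM for culture
data is rate = count/length, tpm = rate/Σrate × 10⁶; all-zero samples
become all-NA. Every aggregation asserts mass conservation, and NA is
always explicit — no silent zeros.

## Diel rhythmicity

Observations are grouped by time-of-day (hours mod 24). For a candidate
peak phase the groups are arranged in a linear chain starting at the
antipodal trough, rising to the peak (⌊K/2⌋ steps) and falling back
(K−1−⌊K/2⌋ steps); the statistic sums, over the K−1 consecutive pairs,
the Mann–Whitney count of concordant cross-group pairs, ties counting ½.
A perfectly monotone rise-then-fall series attains the maximum (the sum
of adjacent group-size products); a constant series scores exactly half.
The observed value is the maximum over the sampled phases (6 candidates
at 4-h sampling; asymmetric rise/fall enumerations are available by
flag).

Significance comes from permuting whole timepoint blocks — all
replicates of a timepoint move together, preserving pairing — and
re-maximizing per permutation; p = (1 + #{null ≥ obs}) / (n_perm + 1),
which is valid (super-uniform) by construction. Defaults: period 24 h,
n_perm ≥ 999, rectangular designs (equal replicates per timepoint)
required. BH q-values use the step-up formula directly. This is a
permutation-calibrated umbrella test in the spirit of rank-based
rhythmicity detection (rise/fall logic, non-parametric); it is *not* a
clone of any published implementation and will not reproduce another
package's exact p-values.

At the diel design (duplicates every 4 h for 4 d) the measured type-I
rate at α = 0.05 lies within [0.03, 0.07] over 1000 null series, and
power exceeds 0.9 with exact modal-phase recovery at log-amplitude /
noise-SD = 2.

## Synthetic data

The generator's defaults are the study conditions: 24 timepoints every
4 h over 4 d starting at 02:00 (so the dawn peak hour, 6, is a sampled
phase), duplicate casts, two size fractions (0.2 µm / 3 µm, splitting
each contig's abundance 40/60), 8 L filtered, 14 spike-in standards with
added copies log-spaced over 10⁵–10⁸, 27 reference leaves in two
monophyletic flavodoxin clades (9 clade I / 12 clade II, 3 and 4 genera)
plus outgroup, sequences of 160 columns, 25 environmental queries at
pendant divergence 0.1 with optional truncation to ≥ 60% of columns.

Diel signal is a **multiplicative cosinor**,
E[abundance](t) = baseline · exp(A·cos(2π(t−φ)/24)), keeping values
positive with a unitless log-amplitude (default A = 1, φ = 6 h on 65% of
clade I contigs; clade II stays flat, echoing the field pattern this
design emulates). Counts are negative binomial with dispersion 0.3
(Var = µ + 0.3µ²), the usual overdispersion scale for transcript counts,
Poisson in the dispersion → 0 limit. Spike-in recoveries are Poisson
around added × a per-sample lognormal efficiency; the reads-per-liter
estimator recovers the true per-sample factor within 5%. Trees are Yule
topologies with i.i.d. exponential branch lengths (mean 0.1) — the
simplest defensible null for a curated reference topology.

**What the generator does not emulate:** real metatranscriptomes have
uneven taxon composition, assembly chimerism and fragmentation,
correlated day-to-day environmental drift, non-sinusoidal waveforms, and
reference trees whose genera are not always monophyletic. Passing the
recovery suite therefore demonstrates that the algorithms are correct and
calibrated under their stated model, not that field data meet that model.

## Numerical and design choices

* Transition matrices via symmetrized eigendecomposition of the
  reversible rate matrix; rows clipped at 0 and renormalized.
* Newick parsing is delegated to dendropy; writing is done in-package
  with shortest-round-trip float formatting, so write→read reproduces
  branch lengths to 10⁻⁹ and jplace edge numbers ({n} annotations,
  preorder) are stable.
* Degenerate inputs: all-gap seed columns → "no match columns" error;
  empty query sequences skipped with a warning; a degenerate (constant)
  calibration score distribution is an error; fewer than 2 full periods
  or fewer than 3 time-of-day groups is an error.
* All stochastic steps take explicit seeds; pipeline re-runs with the
  same configuration are byte-identical.
* Problem sizes in the validation suite (100 oracle queries on ≤ 8-leaf
  trees, 1000 null series, 500-node taxonomies) were chosen as the
  smallest sizes at which the checked rates are stable to a few percent.

## Known limitations

* The PSSM recruiter will not match hmmer bit scores numerically, and
  there is no DNA-space or frameshift-aware search.
* Midpoint attachment slightly misestimates pendant lengths on long
  edges; best-edge identity is what the oracle bound covers.
* The reference tree and its branch lengths are trusted as given; no
  re-optimization, rogue-taxon pruning, or de-novo inference.
* The rhythm test requires rectangular designs and reports phases on the
  sampled time-of-day grid; clock-time interpretation of a phase is up to
  the metadata supplied.
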
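# Methods

## Bond-level kinetic model

Every intron is represented by three phosphodiester bonds — donor
(exon–intron), acceptor (intron–exon) and junction (exon–exon of the
spliced product) — each modeled independently at steady state by
first-order kinetics `dc/dt = α − βc`.  At steady state synthesis
balances decay for any molecular species regardless of mechanism, so α
(normalized counts·min⁻¹) and β (min⁻¹) are defined quantities even
though several microscopic processes (the two transesterification
steps, precursor degradation, product decay) contribute to each bond's
removal.  Interpretation: donor/acceptor β is the splice-site cleavage
rate (half-life ln2/β in minutes); junction α is the rate of completed
splicing and junction β the decay rate of the mature RNA.

During a 4sU pulse of length *t* the labeled pool grows as
`(α/β)(1 − e^(−tβ))` and the pre-existing unlabeled pool decays as
`(α/β)e^(−tβ)`; their sum is always the steady state α/β.  A TT-seq
library contains the labeled pool plus a fraction χ ∈ (0, 1] of the
unlabeled pool (cross-contamination of the streptavidin purification);
an RNA-seq library contains everything (χ ≡ 1).  Expected counts are
scaled by a per-sample factor F > 0 absorbing depth and the global
labeled-RNA fraction.

Counts are negative-binomial with mean E and a single dispersion θ
(`var = μ + μ²/θ`) shared by all bonds and samples.  The NB
log-likelihood is evaluated in gamma-function form, which is continuous
in the count argument; for θ ≥ 1e8 the exact Poisson limit is used
because the gamma form loses all precision to cancellation there.

## Spike-in normalization

Labeled and unlabeled spike-ins enter every sample at constant amounts
before purification.  Expected spike counts are `E = F·p·w` with
extraction probability p and weight w = 1 (labeled) or χ (unlabeled).
Sharing: each unlabeled spike-in has one p for RNA-seq and one for
TT-seq samples; a labeled spike-in has a single p everywhere.  Two scale
conventions close the two flat directions of this model: the geometric
mean of labeled-spike p is fixed (default 0.5), and the geometric mean
of the TT-seq p of unlabeled spikes is tied to their RNA-seq
counterpart, so the average TT-seq depletion of unlabeled material is
attributed to χ rather than to extraction.  Both conventions only move
a global scale into F (and, downstream, into α); β, half-lives and
yields are invariant to them.

All parameters, including θ, are fitted jointly by maximum likelihood
(L-BFGS-B on log/logit-transformed parameters, relative-objective
tolerance 1e-16, 500 iterations, followed by a derivative-free polish
that recovers the digits lost to finite-difference noise).  Background
subtraction for comparing labeled-fraction protocols is
`K/F − χ·K_RNAseq/F_RNAseq`, reported without flooring.

## Rate fitting

Per bond, (α, β) maximize the NB likelihood with expectations above.
The optimizer is BFGS with an analytic gradient over
(log steady-state level, log β) — the RNA-seq samples pin the level and
the time-course shape pins β, so these coordinates avoid the α/β ridge
that makes (log α, log β) poorly conditioned.  Ten independent starts
are drawn with α log-uniform on [1e-2, 1e3] counts/min and half-life
log-uniform on [0.1, 1e4] min; the reported parameters are element-wise
medians over the starts that reach the consensus optimum (within one
log-likelihood unit of the best run).  The likelihood is flat in β
outside the window resolved by the labeling durations, so starts landing
on those plateaus cannot move; restricting the median to near-best runs
keeps the estimate defined by the data whenever the data are informative
and reduces to a median over undirected runs when they are not — which
is precisely the regime the degradation studies quantify.  Bonds with
fewer than 100 reads summed over all samples are excluded (configurable),
and a smooth quadratic wall at |log parameter| = 40 keeps the line search
out of overflow territory.

### Delay model (donors)

A donor bond exists from the moment it is synthesized but cannot be
cleaved before the intron is transcribed up to the branchpoint.  Bond
lifetimes are therefore a fixed lag τ plus an Exp(λ) cleavage time, and
the labeled pool after a pulse of length t is the integral of the
survival function:

```
c_labeled(t) = α·t                                   t ≤ τ
c_labeled(t) = α·(τ + (1 − e^(−(t−τ)λ))/λ)           t > τ
```

with steady state α(τ + 1/λ).  The labeled pool ramps linearly while
cleavage is blocked — the bond is observable during transcription of the
intron — and τ = 0 recovers first-order kinetics exactly.  τ and λ trade
off against each other and are individually weakly identifiable; the
apparent half-life τ + ln2/λ is well determined.  A first-order fit of
delay-generated data underestimates that sum slightly, because the
early linear ramp rises faster (relative to its plateau) than any
single exponential.

### Coupled model (junctions)

Junctions are produced by first-order splicing (rate β_spl) acting on a
precursor synthesized at rate α, and decay at β_deg.  The labeled
product is the standard two-compartment solution

```
P(t) = (α/β_deg)·[1 − (β_deg e^(−β_spl t) − β_spl e^(−β_deg t))/(β_deg − β_spl)]
```

(series limit when the rates coincide within 1e-8 relative; verified
against a numerical ODE solution).  The curve is symmetric under
exchanging the two rates, so from junction counts alone they form an
unordered pair; when the matched acceptor estimate is available its
decay rate — the rate at which the precursor is cleared by splicing —
is taken as β_spl and held fixed, which removes the degeneracy and
anchors the feed rate α = level·β_deg.  A first-order fit of coupled
data reports an apparent half-life close to ln2/β_spl + ln2/β_deg,
erring on the high side because the precursor step delays the labeled
rise.

## Splicing yield

η(acceptor) = Σ_donors α_junction(donor, acceptor) / α_acceptor, with
junction rates from the coupled model and the acceptor rate from the
first-order model (acceptor kinetics carry no transcription delay, so
its synthesis rate is the more robust denominator).  Yields are not
clipped at 1; estimation noise legitimately produces values above it.
Junctions whose coupled fit failed are excluded from the sum and
counted in a per-site completeness column.  Donor-side yield is
computed identically over a donor's junction set behind a flag.

## Read counting

Coordinates are 0-based half-open internally; GTF input is converted
from 1-based inclusive.  Introns are discovered as distinct skipped
(CIGAR N) intervals supported by at least 10 fragments with mapping
quality exactly 255 and no secondary flag (both configurable).  Fragment
strand follows the library protocol (default first-read-reverse).  A
read's aligned blocks must cover both bases flanking a bond contiguously
to count for that bond; a split read counts for the junction only when
its skip equals the intron exactly; a read whose skip partially overlaps
an intron is excluded from all three classes of that intron; mates are
evaluated independently and a fragment counts at most once per
(intron, class).  Discovered introns are classified against the
annotation into annotated / novel-combination / novel-donor /
novel-acceptor / novel-both (intragenic vs intergenic by overlap with
any gene body on either strand).

## Sequence models

Single-nucleotide model: log half-life regressed on the identity of the
20 nt upstream and downstream of donor, acceptor and branchpoint,
one-hot coded relative to the consensus (modal base per position, ties
resolved toward the canonical GT/AG dinucleotides, else alphabetically),
plus GC content of the intron and of the donor and acceptor windows
(centered, so a consensus sequence with average GC predicts exactly the
intercept).  Stage 1 is a Lasso at the largest penalty within one
standard error of the 10-fold CV-minimal MSE; positions whose every
substitution coefficient is zero are dropped; stage 2 refits survivors
by OLS.  The one-SE rule retains a modest number of no-effect positions
with near-zero coefficients — inherent to Lasso selection, and the
planted-signal tests assert exactly that behaviour.  Introns with N in
a window are excluded.  Model error is reported multiplicatively as
median(exp|log(y/ŷ)|).

Octamer model: candidate 8-mers are counted with up to two mismatches
(all overlapping offsets) in four intronic regions — 15–100 nt
downstream of the donor, 100 nt upstream of the branchpoint, between
the branchpoint and 5 nt upstream of the acceptor, and 5–100 nt
upstream of the acceptor, each cropped to the intron.  log2(count+1)
covariates are standardized and selected per region (Lasso, 5-fold CV),
then refined jointly (10-fold CV) together with the single-nucleotide
prediction, per-region GC, log intron length and a first-intron flag.
The variance ledger reports, per feature group, the joint R², the R² of
the group alone, and the drop when the group is removed from the joint
model.  The default candidate vocabulary is the set of 8-mers observed
in the modeled regions — scanning all 65,536 is supported by passing
them explicitly but is disproportionate at the scales the test bed uses.

PWM matching: an octamer's score against a probability matrix is the
probability of its best alignment divided by the maximum probability
any sequence achieves (so the consensus of an equal-length PWM scores
1).  PWMs longer than 8 pad the octamer with neutral N on both sides
(extra N on the right for odd differences); an N contributes the column
maximum.  Matches are ranked per PWM, the top 5% kept, then scores
below 0.9 discarded.

The yield sequence model reuses the single-nucleotide machinery with
log yield (floored at a configurable ε = 1e-3) as the response.

## Synthetic data generator

The generator is the package's test bed and defines its study
conditions.  Defaults: the full 28-sample design (TT-seq and RNA-seq at
2, 5, 10, 15, 20, 30, 60 min × 2 replicates); per-sample depth factors
log-normal (σ = 0.2) around 1; cross-contamination drawn uniformly on
[0.05, 0.2] per TT-seq sample (unlabeled RNA is a large fraction of
short-labeling TT-seq libraries, and χ varies between purifications);
NB dispersion θ = 100, the technical noise scale of spike-in
quantification (≈10% extra-Poisson CV) — appropriate because the
pipeline fits one dispersion on the spike-ins and applies it to all
counts.  Bond parameters are log-uniform: α on [0.1, 100] counts/min,
first-order half-life on [1, 1000] min, transcription delay τ on
[0.1, 10] min, first-step half-time on [1, 60] min, splicing half-time
on [1, 30] min, product half-life on [30, 1000] min.  A coverage knob
rescales per-bond α so the total expected reads across all samples hit
a target interval, matching the quantity the 100-read filter acts on.
Spike-in tables are generated under the normalization GLM with
extraction probabilities satisfying the fit's scale conventions, so a
fit on simulated spikes recovers F and χ on their true scale.

What the generator does *not* emulate: read-level artefacts (mappability,
positional and fragment-length bias, duplicates), isoform structure
(each bond is independent), and biological variability beyond NB count
noise.  Passing recovery tests therefore demonstrates the estimator's
statistical behaviour under the stated noise model, not robustness to
alignment-level systematics.

## Validation studies and problem sizes

`splicekin.studies` packages four simulation studies; each first fits
the spike-in GLM on a simulated spike table and uses the fitted θ for
the kinetic fits, as the real pipeline would.  Relative errors are
multiplicative, exp(|log(est/true)|) − 1, symmetric in over- and
under-estimation (a two-fold error either way is 100%).

* Model-mismatch bias: 1000 bonds under the delay (or coupled) model,
  first-order fits; the median ratio of estimated half-life to
  τ + ln2/λ (resp. ln2/β_spl + ln2/β_deg) is ≈0.88 (resp. ≈1.3) under
  the default conditions.
* Coverage floor: 500 matched-model bonds with total coverage drawn
  uniformly on [10, 99] reads; median relative error ≳120%, the reason
  for the 100-read cut-off.
* Dynamic range: 500 bonds with half-lives fixed at 0.5 min and 3 days
  at coverage 300–1000; median relative error far above 100% — the
  labeling durations carry almost no information about rates outside
  roughly [1 min, 3 days].

These sizes run in a few minutes on one CPU; the per-bond tables the
studies return allow arbitrary re-stratification.

## Known limitations

* τ/λ in the delay model and the unordered rate pair in the
  unanchored coupled model are weakly identifiable by design of the
  experiment, not of the code; only the documented combinations are
  reliable.
* The coupled-model overestimation ratio depends visibly on the
  simulated parameter distributions; under the default log-uniform
  ranges it sits near the top of the expected band.
* Relative uncertainty (exp(sd(log rates)/√n)) assumes the grouped
  rates share a true value; it is a conservative reproducibility
  summary, not a per-bond standard error.
* The GTF reader extracts exon/gene records of the GENCODE dialect
  only; intron classification trusts the annotation's strand.
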
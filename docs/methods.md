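# Methods

## Model overview

`medflydrive` implements an agent-based, discrete-generation model of homing
gene drive in a medfly-like life cycle, together with the cross-count
statistics used to estimate drive activity from laboratory homing assays.
The model tracks, for every individual, a karyotype (XX/XY), a diploid
genotype at the loci the active drive architecture touches, and a flag for
whether the egg received maternal *transformer* (*tra*) product. Sex and
fertility are pure functions of these:

* XY → male (*MoY* dominance), always fertile;
* XX → female iff maternal *tra* provision arrived **and** at least one
  zygotic *tra* allele is functional; otherwise a viable, fertile XX male;
* a female is sterile iff she lacks a functional allele at any
  female-fertility locus her design targets (the fertility genes are
  recessive).

Allele classes per target locus: wild type (the only cleavable class), the
drive construct (inserted into and disrupting its home gene), and resistance
indels R1 (functional) and R2 (non-functional). The construct can exist only
at its design's home locus; a trans-targeted locus is merely cut.

## Germline transmission

Within a construct carrier's germline, each wild-type allele at each targeted
locus is cleaved independently with probability *c*. Cleaved alleles repair
in uniformly random order: with probability *h* by HDR — copying the
homolog's current state, which is homing when the homolog is the construct
(home locus only), resistance copying when it is R1/R2, and restoration when
it is wild type — and otherwise by NHEJ (R2 with probability *r2*, else R1).
When both alleles are cleaved, the first to repair has no intact template and
must end-join; the second may then copy the first's repair product. This
sequential-resolution rule is what makes "R-allele homing" well defined
without a template paradox. Cleavage and repair are resolved fresh at every
meiosis; parents are never mutated.

The resulting hemizygote transmission rate has the closed form
T = (1 + c·h)/2, and the disrupted-site fraction among non-carrier gametes is
m = c(1 − h)/(1 − c·h). An exact enumeration of all cleavage/repair paths
(`gamete_distribution`) serves as the oracle for both the scalar and the
vectorised samplers; the test suite checks the empirical frequencies of the
samplers against it at 3-standard-error resolution.

## Maternal effects

Two distinct maternal effects are modelled, both conditional on the mother
carrying the construct:

* **Deposition.** Cas9 carried over in the egg cleaves each zygotic wild-type
  allele at each targeted locus independently with probability min(1, k·c),
  repaired by NHEJ only (no homing in the embryo); deposition can create
  resistance alleles but never the construct. The proportionality constant
  *k* defaults to 1 (embryonic rate equals germline rate) and is exposed in
  every config.
* ***tra* provision.** For *tra*-targeting designs, the mother's own
  cleavable (wild-type) *tra* alleles may be disrupted in the nurse cells and
  oocyte, each independently with probability *c*, drawn fresh per offspring
  (nurse-cell mosaicism acts like a per-egg Bernoulli). Provision fails iff
  no functional maternal allele remains; an R1 allele, having lost the target
  site, always secures provision. A provision failure makes all affected
  progeny male regardless of genotype.

Deposition is applied to the zygote before sex determination, so a *tra*
allele destroyed in the embryo counts against femaleness.

Paternal Cas9 carryover is not modelled (observed only sporadically, at the
0.05% level) and intersex phenotypes — which arise experimentally from
somatic mosaic *tra* disruption — are outside the model: conversions are
complete male or female, and males are always fertile. Passing tests
therefore say nothing about somatic leakage, partial *tra* function, dosage
effects or intersex sterility in real strains; the data model still reads
INTERSEX/MOSAIC rows so that real-style tables can be analysed.

## Population simulation

Generations are discrete and non-overlapping with a constant census of
N individuals (default 1000). Each offspring independently samples a mother
uniformly from the fertile females and a father uniformly from the fertile
males (random mating with replacement; no mate limitation), receives one
gamete from each parent, takes Y from an XY father with probability 1/2 (XX
fathers only transmit X), then undergoes deposition, provision and phenotype
assignment. Suppression manifests purely as collapse of a reproductive
class: extinction is recorded at the first generation with zero fertile
females or zero fertile males (including the final generation of the
horizon), at which point the census drops to zero. There is no density
model, age structure, migration or fitness cost of carrying the construct
(none was measured experimentally).

The default release is 500 wild-type females, 250 wild-type males and 250
hemizygous drive males — a 12.5% construct frequency — run for 20
generations. Replicates use spawned `numpy` SeedSequence substreams of the
master seed, so replicate *r* is reproducible in isolation and results are
bitwise stable under a fixed seed.

The population is stored column-wise in numpy arrays and whole generations
are produced with vectorised draws; this is an implementation choice only.
Equivalence with the per-individual semantics is established by (a) checking
batch gamete frequencies against the exact enumeration, and (b) comparing
the stochastic generation-1 construct frequency with the deterministic
infinite-population expectation assembled from per-parent analytic gamete
distributions.

## Parameter sweeps and smoothing

Sweeps cover any subset of the axes (*c*, *r2*, *h*) with a configurable
replicate count per grid point. Two presets mirror the two standard views of
the design space, each 36 grid points × 10 replicates = 360 simulations:

* `extinction-surface`: *c* ∈ [0.5, 1] × *r2* ∈ [0, 1] at fixed *h* = 0.95,
  20 generations, reporting extinction fraction;
* `duration-surface`: *c* ∈ [0.5, 1] × *h* ∈ [0.5, 1] at fixed *r2* = 0.99,
  reporting mean time to extinction (over extinct runs only; a
  censoring-aware alternative that counts survivors at the horizon is
  available via a flag).

The 6×6 × 10 decomposition of the 360-run budget, and the axis ranges
(cleavage and HDR restricted to the upper half where drives are viable), are
this package's defaults; both knobs are configurable. The mean duration is
taken over extinct runs only because a censored mean would conflate speed
with likelihood of suppression.

The extinction response is smoothed with a 2-D local polynomial (LOESS-style)
regression written in-package: axes are standardised to unit scale, each
evaluation node uses its ⌈span·n⌉ nearest data points, tricube weights
(1 − (d/bw)³)³ feed a weighted least-squares polynomial of total degree
`degree`, and the fitted extinction rate is clamped to [0, 1]. Defaults:
span 0.75, degree 2 — the conventional local-regression defaults. Spans
above 1 inflate the bandwidth beyond the data diameter so the fit approaches
the global polynomial fit, which the tests exploit as a limit check. A
window holding fewer positively weighted points than polynomial coefficients
raises an error rather than silently extrapolating.

## Cross statistics and synthetic crosses

Homing assays are summarised from tidy count tables (replicate × marker ×
sex phenotype × eye phenotype). Transmission uses the Wilson score interval
(better behaviour near 0/1 at these sample sizes); goodness of fit is a
1-degree chi-square against a binary expectation without continuity
correction, refusing expected counts below 1. Statistics are computed both
pooled over replicates and per replicate, since both conventions appear in
practice; the output labels which was used.

The (c, h) inference inverts (T, m) as c = (2T − 1) + m(2 − 2T),
h = (2T − 1)/c, with h indeterminate (NaN) at c = 0. It assumes (i) every
NHEJ repair at the scored locus disrupts the visible phenotype (r2 = 1
there; in-frame repairs that preserve pigmentation would bias m downward),
and (ii) all disruptions are germline events. Because a transgenic mother's
deposited Cas9 adds embryonic disruptions, assumption (ii) holds only for
paternal crosses (or k = 0); parameter-recovery validation therefore uses
paternal eye-mutant crosses, and maternal-deposition-rate estimation from
mosaics is left as future work.

The synthetic generator draws progeny from the same germline kernels as the
simulator. The scored eye gene is modelled as a generic recessive visible
marker with transmission mechanics identical to the construct's home locus
(the construct homes into the eye gene, disrupting it); eye-mutant mates are
homozygous for a non-cleavable, non-functional allele. An offspring is WHITE
iff both eye-locus alleles are non-functional. MOSAIC eye phenotypes and
INTERSEX progeny are never generated, consistent with the absence of a
somatic-leakage process in the model.

## Numerical and design choices

* Allele states are int8 codes (wild 0, construct 1, R1 2, R2 3); exact
  enumeration probabilities are required to sum to 1 within 1e-12.
* A single cleavage-rate parameter applies at the home and trans-target loci
  (one Cas9, coinherited gRNAs).
* The smoother's degenerate case — an evaluation node coinciding with all
  of its nearest neighbours (zero bandwidth) — returns the mean of the
  coincident values.
* Problem sizes in the test suite and the reproduction script are chosen to
  keep full runs fast: suppression scenarios use 100 replicates at census
  1000, the sweep-reproducibility check runs its 360 simulations at census
  250 over 10 generations, and oracle comparisons use 10^5 draws. All
  quantities reported by `scripts/acceptance.py` are computed at run time
  from these scenarios.

## Known limitations

* Constant-census regulation with full density compensation; no partial
  suppression dynamics below N, so "time to extinction" reflects genetic
  collapse, not demography.
* No somatic Cas9 expression: the model cannot reproduce the intersex
  fractions or mosaic-expression phenotypes observed in real *tra*-drive
  strains.
* Maternal provision treats the nurse-cell/oocyte compound as a single
  per-egg Bernoulli event; correlated provision within egg clutches is not
  modelled.
* The (c, h) inference is biased when in-frame NHEJ repairs preserve the
  scored phenotype or when maternal deposition contributes disruptions.
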
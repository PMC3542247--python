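# Methods

## Scope and representation

`polymeiosis` simulates gamete formation in diploids and tetraploids and
gene-drops founder-labelled chromosomes down pedigrees. Chromosomes are
abstract genetic maps in centiMorgan; there is no sequence or physical
coordinate. Every chromosome copy is a `HaploStruct`: an ordered list of
`(start, founder allele)` segments with half-open extents `[start,
next_start)`. A position exactly at a crossover takes the recombined
(distal) allele; crossover positions are continuous, so ties with marker
positions are measure-zero and the fixed rule only serves determinism.
Founder *i* of ploidy *P* owns founder alleles *iP* .. *iP*+*P*−1, one per
homolog slot, which makes allele IDs globally unique and lets any
descendant chromosome be decoded to its founder origin at every position.

Univalents, trivalents and unbalanced gametes are outside the model, as
are ploidies other than 2 and 4, phenotype generation, and
scoring-error/missing-data injection (all straightforward to apply to the
error-free output downstream).

## Chiasma process

Crossovers are generated per paired structure by a renewal process running
from one telomere to the other. Distances between successive chiasmata are
exponential with mean 0.5 Morgan per paired chromosome pair (two chiasmata
per Morgan in a bivalent), or, with chiasma interference, Gamma with shape
2.63 and the same mean (scale = mean/shape). The shape value is the one
that makes per-chromatid recombination track the Kosambi map function;
without interference the process is Poisson and recombination follows
Haldane. The "Morgan" here is defined by chiasma counts per chromatid —
one crossover per chromatid per Morgan — which coincides with the
map-distance definition for bivalents and keeps map length meaningful for
quadrivalents, where the parallel configuration pairs four chromosomes and
therefore runs at a 0.25 Morgan mean spacing (four chiasmata per Morgan,
same per-chromatid rate).

Because the gamma renewal process is not memoryless, it is burnt in
starting 10 Morgan before the chromosome (first gap exponential, then
gamma gaps) so that it is stationary at position 0; 10 Morgan is 20+
renewal means, stationary to numerical precision, and the burn-in costs
only ~20 extra draws per structure. The exponential process needs no
burn-in. A structure may legitimately receive zero chiasmata; no obligate
chiasma is enforced.

No chromatid interference: each chiasma chooses one chromatid of each
paired chromosome uniformly, independently of every other chiasma.

### Strand bookkeeping

A chiasma at *x* is applied as a tail swap: the two strands exchange all
content at positions ≥ *x*. Two bookkeeping rules make the four-strand
accounting exact:

* **Axis occupancy.** After a crossover, each of the two strands continues
  distally along the other chromosome's pairing axis. Chiasmata are
  applied in ascending position order and each chooses among the *current*
  occupants of its two axes. Without this rule (choosing by original
  strand identity), crossovers proximal to an interval make later
  crossovers in the interval silently ineffective and the simulated
  recombination falls measurably below Haldane (≈0.27 instead of 0.3161
  over 50 cM).
* **Centromere units.** Each strand is attached to a physical centromere.
  A crossover proximal to the centromere moves the centromere region with
  the exchanged tail, so the two strands also trade centromere membership.
  Units are structural (per homolog slot), not inferred from alleles, so
  they remain well-defined for non-founder parents whose homologs can
  share a founder allele at the centromere. This rule is what guarantees
  that every tetraploid gamete receives its two chromatids from two
  different parental centromeres — equivalently, zero double reduction at
  the centromere itself — in every configuration.

## Pairing and configurations

At each telomere of a tetraploid chromosome set the four homolog slots
partition into two pairs; with preferential-pairing fraction *p* the
matching (same-subgenome) partition has probability *p* + (1−*p*)/3 and
the other two (1−*p*)/3 each. In natural mode the two telomeres draw
independently: equal draws give two bivalents, different draws a
quadrivalent, so P(quadrivalent) = 1 − [(*p* + (1−*p*)/3)² +
2((1−*p*)/3)²]. In forced mode the configuration is a Bernoulli draw on a
per-chromosome quadrivalent fraction and pairing happens within that
constraint: for bivalents one telomere draw is used at both ends; for a
quadrivalent the bottom pairing is drawn from the preferential
distribution renormalized over the two partitions different from the top.
A quadrivalent is parallel-type with a configurable probability
(default 0: cross-type).

Subgenome identity in non-founders is positional: the maternal gamete's
chromatids fill homolog slots 0..*P*/2−1 in order, the paternal the rest.
After quadrivalent recombination a chromatid can be a subgenome mosaic;
how preferential pairing should treat such mosaics is biologically
unresolved, and the positional convention is a documented bookkeeping
choice, not a biological claim.

### Cross-type quadrivalent and the exchange point

A cross-type quadrivalent has four branches: two pairing chromosome tops
(per the top pairing) and two pairing bottoms, meeting at a chromosome
exchange point that varies between meioses. The exchange point is located
by a frontier race: four virtual renewal streams (two per side, chiasma
statistics as above) advance inward from the telomeres; the pending step
closest to its own telomere advances its frontier, a step that would cross
the opposite side's frontier closes its stream, and the exchange point is
the midpoint of the final gap. This yields a unimodal distribution peaked
at the chromosome center, more sharply for longer chromosomes.

The race's own steps are then discarded and the actual chiasmata are drawn
as fresh streams truncated at the exchange point (top branches over
[0, X), bottom over (X, L], entering from their telomeres). Reusing the
race's steps as chiasmata would condition territory on chiasma density —
event-rich streams win more territory — inflating chiasma density ~30%
overall with a two-fold pile-up around the collision, and pushing
recombination near the center above even the parallel-quadrivalent level.
With the two-stage design the chiasma density stays at the stationary rate
inside each branch territory, and cross-type recombination falls between
the bivalent and parallel levels at long intervals, as expected. There is
no experimental evidence for any particular exchange-point distribution,
and published closed forms for cross-type recombination assume a uniform
one, so numerical cross-type values are mechanism-dependent and treated as
qualitative references only.

Recombined cross-type chromatids can carry segments of three founder
chromosomes; parallel-quadrivalent chromatids of all four.

## Meiotic divisions

First division: each bivalent sends one centromere to each pole. The four
centromeres of a quadrivalent are partitioned into two pairs uniformly
over the three possible partitions (random partition is the default and
the empirically supported model). For cross-type quadrivalents an
alternative model is available in which the two chromosomes paired on the
centromere's side of the exchange point always move to opposite poles (the
two compatible partitions equally likely); it is undefined for parallel
quadrivalents and rejected there. Second division: each centromere splits,
its two chromatids going to the two daughter gametes with independent
random orientation. All stages are independent between chromosome sets, so
non-homologous chromosomes assort independently.

## Statistics ("test mode")

The test harness runs *n* independent meioses of a single founder, samples
one of the four gametes uniformly per meiosis, and records the founder
allele of every chromatid at a set of test loci. Recombination between two
loci is the fraction of chromatids whose founder alleles differ there — a
double crossover restoring the same founder allele counts as
non-recombinant, matching the observational definition behind map
functions. Double reduction at a locus is the fraction of gametes whose
two chromatids carry the same founder allele. Standard errors are binomial
on pooled counts; comparisons with closed forms are reported as z-scores
rather than the t-tests one would use for replicated batches, since the
purpose is validation, not hypothesis testing.

Expected behaviour validated by the test suite and the acceptance script:
bivalent recombination matches Haldane (no interference) or Kosambi
(interference, within the documented small bias of the shape-2.63 gamma
model, absorbed by a tolerance of max(3 SE, 0.002)); parallel-quadrivalent
recombination reaches 0.55 over 100 cM (above the diploid 0.5 ceiling);
double reduction is 0 at the centromere, rises with distance, and
approaches 1/7 — the probability that a given allele meets its sister copy
when the eight chromatids assort randomly — far from it; quadrivalent
frequency follows the pairing closed form. The DR limit is asserted on
parallel quadrivalents, where it is length-independent; cross-type DR at
matched distances is slightly depressed on long chromosomes (a known
consequence of the center-peaked exchange point) and is checked
qualitatively.

## Synthetic data and realism

All populations are generated internally from labelled founders; no
external data are used. The generator produces complete, error-free,
ordered genotypes under idealized assumptions: no univalents or aneuploid
gametes, no fitness selection, position-independent recombination rates,
and a single centromere per chromosome. Passing tests therefore
demonstrate internal consistency with the stated genetic models, not
agreement with any particular organism's cytology; genotyping error,
missing data and segregation distortion must be layered on downstream if
realism demands them.

## Problem sizes and numerics

Validation simulations use 10^5 meioses per statistic (10^6 draws for
pairing-only statistics), which puts three binomial standard errors at
2–3 × 10^-3 for the recombination fractions of interest; the unit-test
suite uses 2–3 × 10^4 for speed. One `random.Random` stream drives an
entire run, seeded once; identical seeds give byte-identical outputs.
Segment lists remain canonical (adjacent segments always differ in
allele) by construction through every tail swap, and floating-point cM
positions round-trip exactly through the text output format.
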
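# Methods

## Scope and data model

`splicemeta` analyses tables of per-replicate inclusion/skipping read
counts for alternative-splicing events across multiple independent
two-group studies (groups are labelled `fat` / `thin` after the motivating
sheep fat-tail comparison; nothing else in the machinery is
species-specific). Skipped-exon (SE) events are enumerated directly from a
GTF annotation: a cassette triple (A, B, C) where one transcript of a gene
contains A, B, C as consecutive exons and another contains A, C adjacently
without B. "Consecutive" means no other exon of the same transcript lies
between them, and exon identity is by exact coordinates; novel junctions
are not discovered — events come from annotation only. The other event
classes (MXE, A5SS, A3SS, RI) are accepted as precomputed rows of the
event-table format rather than derived from annotation; the analyses this
package was built around end up entirely in the SE class, so SE is the
class with first-class enumeration support. Events spanning overlapping
genes keep the `gene_id` their GTF records carry; no overlap resolution is
attempted.

Internally all coordinates are 0-based half-open; GTF input (1-based
inclusive) is converted on read and BED output is written 0-based
half-open. An event's identity is the canonical tuple (class, chromosome,
strand, target start/end, upstream-flank end, downstream-flank start),
rendered as the `event_id` string. The same key is used by both statistical
arms, which is what makes cross-arm matching exact rather than
interval-overlap based.

## PSI quantification

Replicate PSI is the effective-length-normalised inclusion fraction
`ψ = (I/lI)/(I/lI + S/lS)`. Effective lengths count distinct read
placements able to support each isoform with a 1 bp anchor: `lI = 2(L−1)`,
`lS = L−1` in junction-only (JC) mode; JCEC adds `max(0, e−L+1)` exon-body
placements to `lI`. The anchor length and the JCEC body term are a
reconstruction of standard junction-counting practice — the quantity that
matters downstream is the 2:1 junction-opportunity ratio they preserve.
Group PSI is the unweighted mean of non-missing replicate PSIs (replicates
with `I = S = 0` are dropped, not imputed), and ΔPSI = ψ_fat − ψ_thin.

## Count arm

Within one study, `I_r ~ Binomial(I_r+S_r, θ_g)` per replicate with
`θ_g = lI ψ_g/(lI ψ_g + lS(1−ψ_g))`. ψ is estimated by bounded 1-D
maximisation on [1e−9, 1−1e−9] (tolerance 1e−8; the clamp avoids log 0),
separately per group under H1 and pooled under H0; `2(ℓ̂_H1−ℓ̂_H0)` is
referred to χ²(1). No permutation fallback is provided for tiny samples, so
p-values at 1 replicate/group and low depth are approximate. FDR is
Benjamini–Hochberg within each study across all tested events jointly (not
per event class), and a call requires strictly FDR < 0.05.

This is deliberately a plain binomial LRT, not a hierarchical
replicate-variance model. Under extra-replicate dispersion it is
anticonservative; the `overdispersion=ρ` option swaps in a beta-binomial
likelihood with the same mean structure (mean θ, variance inflated by ρ),
which restores calibration when replicates genuinely scatter beyond
binomial noise. The cross-study consensus (below) is the second, structural
defence against per-study miscalibration.

## Graph arm

Transcripts of a gene collapse to a contiguous splice graph: nodes are the
maximal exonic segments obtained by splitting the union of exons at every
distinct exon boundary; each transcript's exon chain induces directed edges
between the consecutive segments it covers. Node PSI is the raw
inclusion-path fraction `inc/(inc+exc)` — unlike the count arm it is not
length-normalised, which mirrors how path-based quantifiers report
inclusion and means the two arms measure slightly different scales (for an
SE node under JC lengths, the raw fraction is `2ψ/(1+ψ)`).

For differential calling, counts are pooled within each group (SE-event
calls attach to the node whose interval equals the event target) and given
a uniform Beta(1, 1) prior: `ψ_g | data ~ Beta(inc_g+1, exc_g+1)`. ΔPSI is
the exact difference of posterior means; the posterior probability is the
Monte-Carlo estimate (default 10,000 draws, default seed 20240129) of
`P(sign(ψ_fat−ψ_thin) = sign(ΔPSI))` — sign agreement with the point
estimate, not `P(|Δ|>c)`; the two-threshold call (probability > 0.8 strict,
|ΔPSI| ≥ 0.1 inclusive) tests effect size separately, which is why the
sign-specific probability was chosen. The reconstruction is documented as
such, not asserted to be numerically equivalent to any external tool; in
particular no GC/positional bias correction is modelled (that requires
sequence-level data). Draws are taken in sorted event order so results are
invariant to input row order.

## Consensus filter

Per arm, an event passes with sign s when ≥ `min_studies` (default 3)
studies have significant calls with sign(ΔPSI) = s; ΔPSI = 0 supports
neither sign, and events reaching the threshold with both signs are
excluded as ambiguous. An event is **stable** when it passes in at least
one arm and the other arm contributes ≥ `min_other` (default 1) significant
call of the same sign in any study (the confirming study may coincide with
a supporting one; no disjointness is required). Requiring the confirmation
to share the sign is a design choice (`require_sign_match` can disable it):
a sign-discordant "confirmation" would contradict the same-trend rationale
of the whole filter. The ≥ 3-study rule is evaluated per arm, not on the
union of arms — pooling arms would let two weak 2-study signals masquerade
as one 4-study signal. The reported mean ΔPSI averages the primary arm's
supporting studies (when both arms qualify, the arm with more supporting
studies leads; count arm on ties).

Intersection counts use UpSet semantics: each event belongs to exactly the
subset equal to its full set of significant studies, and subsets with fewer
than `observation_threshold` (default 5) events are omitted.

Note the one non-monotonicity worth knowing: lowering `min_studies` can
*remove* an event from the stable set by turning it ambiguous (both signs
now reach the lower threshold). Among events with a single-sign support
profile the filter is monotone in both thresholds.

## Enrichment

Stable genes are tested against GMT gene-set collections with the exact
hypergeometric upper tail `P(X ≥ x)`, BH-corrected across the collection's
terms; significance requires p < 0.01 and FDR < 0.2. The background
defaults to the union of the collection's genes and should be set to the
tested universe (genes carrying ≥ 1 enumerated event) when known — this is
a local stand-in for web enrichment services, not a replication of any
particular service's background or statistic.

## Synthetic data generator

The generator emulates the seven-study design: replicate layout fat
(4,3,3,3,3,3,3) / thin (4,3,3,3,3,4,3), read lengths
(150,75,150,150,101,150,150). Baseline PSI ~ Uniform(0.05, 0.95) per
event; a fraction `frac_das` (default 0.1) of events are differential with
a fixed |ΔPSI| (default 0.3) split symmetrically ±effect/2 around baseline
(clipped to [0.01, 0.99] with a warning) and a random sign shared by
`study_sharing` studies (default 5 of 7, so both the pass and fail regimes
of the ≥ 3-study rule occur in one simulation). Replicate PSIs are
Beta-distributed around the group PSI with dispersion ρ (mean ψ, variance
ρψ(1−ψ); the parameterisation degenerates cleanly to no extra noise at
ρ = 0, default 0.05). Totals are Poisson(depth, default 100); inclusion
counts are binomial at the length-distorted proportion θ using JC effective
lengths.

What it does *not* emulate: alignment artefacts, multi-mapping, GC bias,
correlated events within a gene, study-level batch shifts in baseline PSI,
and library-size variation beyond Poisson. Passing tests therefore
demonstrate correctness of the statistics and the consensus logic under the
stated generative model, not robustness to every failure mode of real
RNA-seq.

## Calibration and benchmark conditions

Two standing benchmarks (run both by the test suite and by
`scripts/acceptance.py`) fix the study conditions:

* **Null calibration** — one study, 3 replicates/group, depth 100, 5,000
  null events, ρ = 0: the binomial LRT's p-values are checked for
  uniformity (type-I error at p < 0.05, KS distance). ρ = 0 because the
  calibration statement concerns the LRT under its own model; under ρ > 0
  the plain binomial arm is anticonservative by design (see above).
* **Recovery** — 500 events, 20% differential, |ΔPSI| = 0.3, sharing 5/7,
  depth 200, ρ = 0.05: per-carrying-study mean ΔPSI recovery, stable-set
  recall and empirical false-discovery proportion. The pipeline here uses
  the beta-binomial count arm with ρ matched to the generative dispersion —
  the variant exists precisely for overdispersed data; with the plain
  binomial arm both arms' per-study false calls compound and the stable set
  FDP degrades badly, which is itself an instructive property of the
  consensus rule (it filters the graph arm's ~20% per-study null call rate
  down to a few percent, but cannot fully rescue two simultaneously
  miscalibrated arms).

Problem sizes (5,000 null events; 500-event recovery runs) were chosen so
each benchmark completes in seconds at tight Monte-Carlo error; both are
deterministic given the seed.

## Numerical choices and degenerate inputs

* ψ MLE: bounded scalar optimisation, tolerance 1e−8, boundary clamp 1e−9.
* LRT statistic floored at 0 (numerical maximisation can undershoot by
  < 1e−10 on exact-null data).
* Posterior probability at ΔPSI = 0 is reported as P(diff > 0) = 0.5 under
  the symmetric posterior.
* Events with an all-zero group in a study are skipped for that study and
  logged, in both arms and in group-delta computation.
* BH q-values are clipped to 1 and returned in input order.
* The toy fixture's counts are fully deterministic, so its per-arm calls —
  and hence the golden stable set of 4 events (1 at `min_studies=4`) —
  follow exactly from its count templates.

## Known limitations

The count arm is not a hierarchical replicate-variance model and its ρ is
supplied, not estimated. The graph arm's posterior is a conjugate
reconstruction with pooled counts — replicate identity is lost there by
construction. MXE sign orientation follows the upstream alternative exon
by convention. Consensus is vote counting, not meta-analytic pooling of
p-values or effect sizes; that is faithful to the integration strategy the
package implements, and deliberately so.
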
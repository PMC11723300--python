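# Methods

This note records the models, conventions and parameter choices behind
`barcodekit`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Sequence statistics

Length statistics use ungapped per-sequence lengths; GC content is
100·(G+C)/(A+C+G+T) with gaps and IUPAC ambiguity codes excluded from both
numerator and denominator. Site classes are assigned per alignment column
after dropping rows that carry a gap or ambiguity in that column: columns
with fewer than two remaining bases are excluded entirely; one state left →
conserved; otherwise variable, and variable columns are
parsimony-informative when at least two states each occur at least twice,
else singleton sites. Nucleotide diversity π is the mean pairwise
p-distance with pairwise deletion — MEGA's default deletion policy, chosen
because it is the de-facto standard for barcode surveys and because any
pair with zero comparable sites is then an explicit error rather than a
silent NaN.

## Distances

Transitions are A↔G and C↔T; all other mismatches are transversions, with
proportions P and Q taken over the pair's comparable sites (pairwise
deletion again). K2P is d = −½·ln((1−2P−Q)·√(1−2Q)); pairs for which the
log argument is non-positive are *saturated* and flagged inapplicable (NaN)
rather than raising — pooled summaries exclude them and report the count.
Both p-distance and K2P are first-class because barcode studies commonly
quote K2P for the distance analysis while running delimitation tools on
p-distances; every downstream table records which model produced it.

The bootstrap resamples alignment columns with replacement (the standard
site bootstrap) and reports the standard deviation of per-replicate
distances as the SE; replicates in which a pair loses all comparable sites
or saturates are skipped for that pair and counted.

## Barcoding gap

Distances are pooled intra- vs inter-specifically by the taxonomy table.
The per-species gap criterion is strict: max(intra) < min(inter). Singleton
species (one voucher) have no intraspecific variation; they are judged on
min(inter) alone with max_intra = 0 and a `singleton` flag, and reported —
never dropped — because in sparse regional surveys most species are
singletons and hiding them would overstate the evidence. Marker
combinations are built by concatenating the aligned markers over the
samples present in all of them, and distances are recomputed on the
concatenation (not averaged across markers).

## MOTU delimitation

**ABGD.** For each prior P on a log-spaced ladder (defaults mirror the
public web server: p_min = 0.001, p_max = 0.1, 10 steps, gap-width
multiplier X = 1.5), the ranked pairwise distances are scanned for the
first gap that (a) is not entirely below P — distances below P are presumed
intraspecific, so only a jump crossing or above P can be the barcode gap —
and (b) whose width exceeds X times the running mean of the distances at
and below its lower edge. Samples linked by any distance at or below the
gap's lower edge form one MOTU (connected components); the procedure
recurses within each MOTU and stops when a group has fewer than 3 samples
or shows no qualifying gap. One partition is reported per prior; the
headline partition is the one with the modal MOTU count across priors, ties
broken toward fewer MOTUs (the conservative, lumping direction).

**ASAP-style ranker.** Single-linkage agglomeration proposes one candidate
partition per distinct merge height. Each candidate is scored by the mean
of two ranks: the width of the gap to the next merge height (larger =
better-isolated threshold) and the separation statistic mean(inter) −
mean(intra) it achieves (larger = tighter clusters). This is a rank-based
analogue of the published ASAP score, which combines a panmixia
probability with gap width; the exact probability model is deliberately
not reproduced, and every report header records the scorer used.

**Discrimination.** A species is recovered iff all its samples fall in one
MOTU and that MOTU contains no other species — the strictest reading of
"identification success", stated in output metadata because looser readings
(e.g. ignoring lumping) inflate rates.

## Identification

Queries are matched against a local reference library by global pairwise
alignment (match +1, mismatch −1, gap open −2, extend −0.5); percent
identity is computed over aligned comparable positions and coverage over
the query's ungapped length. The best hit maximises identity, then
coverage, then lexicographic reference id (a deterministic tie-break).
Leave-one-out (`exclude_self=True`) is the default evaluation. A local
library replaces live database queries because the latter are
database-version-dependent and irreproducible; the E-value screen of
BLAST-style searches is replaced by an explicit `min_identity` filter,
recorded in output metadata. Verdicts are hierarchical by construction: a
conspecific best hit also counts as congeneric and confamilial, so species
success rates can never exceed genus rates, nor genus exceed family.

## Monophyly

Monophyly is tested on unrooted bipartitions: a species with ≥2 tips is
monophyletic iff some edge separates exactly its tips from all others, so
re-rooting cannot change verdicts. The support of the defining split gates
"supported" status: support must strictly exceed the threshold (default
95, the usual ultrafast-bootstrap convention); a monophyletic species
whose split carries no recorded support counts as unsupported while a
threshold is active. When the species' own clade and a complement match
both exist (a rooting artefact near the root), the edge subtending the
species' own tips is preferred as the defining split. Trees without any
supports (e.g. the NJ plumbing trees) are scored on monophyly alone at
threshold 0. Singletons are reported but excluded from the headline rate
by default; the flag `include_singletons` flips that, and reports always
state the denominator convention.

The NJ builder is plumbing so the scoring machinery can run without an
external ML program: standard neighbor joining, negative branch-length
estimates clamped to zero, exact on additive matrices (verified to 1e−9
path-length error in tests). It is not a substitute analysis method —
real monophyly assessments should consume externally inferred trees with
supports.

## AHP

Weights are the normalized principal eigenvector of the positive
reciprocal judgment matrix (power iteration to relative tolerance 1e−10);
the row geometric-mean weights are kept as an independent cross-check, and
on consistency-acceptable matrices the two agree to well under 0.02 per
component. Consistency uses λmax: CI = (λmax − n)/(n − 1), CR = CI/RI with
Saaty's random indices (n = 1..9 → 0, 0, 0.58, 0.90, 1.12, 1.24, 1.32,
1.41, 1.45); CR < 0.1 is acceptable.

The composite score is S = Σᵢ wᵢ·(pᵢ/pᵢᵐᵃˣ): each criterion contributes
its full weight at its top level, so S = Σwᵢ when every criterion is
maximal and the analytic minimum (every criterion at its lowest level) is
Σᵢ wᵢ/pᵢᵐᵃˣ ≈ 0.170 under the default scheme. How published surveys
aggregate indicator points into their printed scores is generally not
stated, so this normalization is a *declared convention*: an alternative
(points divided globally by 9) is selectable, and every report names the
convention used. No claim is made that either convention reproduces any
particular published score column from unpublished indicator assignments.

Class boundaries are class 1: S ≥ 0.60, class 2: 0.40 ≤ S < 0.60,
class 3: S < 0.40. Putting S = 0.60 in class 1 follows the bundled survey
table, which lists species scored exactly 0.60 in its top class. Ranking
is by descending S with alphabetical tie-break.

The default 13-criterion scheme (endangerment 0.3938, genetic value
0.3270, economic value 0.0655, endemism 0.0545, …) carries its published
expert weights, which sum to 1.0001 — they are used as printed rather than
renormalized, and the scheme validator tolerates 1e−3.

## Synthetic data

The generator emulates the *structure* every stage assumes, at a reduced,
test-friendly scale (default: 3 families × 2 genera × 2 species, 1–3
vouchers per species, three markers shaped like ITS / *matK* / *rbcL* with
lengths 700/800/600, GC targets 0.56/0.34/0.44 and between-congener
divergence targets 0.14/0.13/0.06 — preserving the qualitative ordering
ITS ≈ *matK* > *rbcL* of real surveys).

Sequence evolution is a two-rate per-site substitution process: a mutated
site undergoes a transition with probability κ/(κ+1) (default κ = 2), else
one of the two transversions uniformly. This is the minimal model under
which K2P is the matched estimator, which is exactly what makes parameter
recovery a meaningful test. Family, genus and species ancestors radiate
from their parent in a star phylogeny at each level, with one-sided rates
set to half the target pairwise divergence; the star shape makes the
configured between-species divergence a floor on inter-specific distance,
so a configured gap (intra target < inter target) is realized up to
binomial site-sampling noise. Configurations claiming a gap while their
divergence targets overlap are rejected. The no-gap variant widens
individual-level variation to 1.5× the inter-species target and draws
species separations from U(0, inter/4), so the two distance distributions
genuinely interleave.

Deliberately **not** modelled: indels and alignment error (sequences are
generated aligned), recombination, rate heterogeneity across sites,
base-composition drift, and realistic coalescent branching (the star
phylogeny trades realism for a guaranteed divergence floor). Passing tests
therefore demonstrate correctness of the algorithms under their matched
model, not robustness to alignment artefacts or heterogeneous real data.

Judgment matrices are simulated by perturbing a consistent matrix with
symmetric log-normal noise (reciprocity preserved exactly) and rejecting
draws with CR ≥ 0.1, mirroring AHP practice where inconsistent matrices
are sent back for re-elicitation.

Every generator is a pure function of its configuration and seed
(independent named RNG streams per component, spawned from one seed
sequence), so identical configs give byte-identical outputs.

## Problem sizes

The test suite and the acceptance script use 50-replicate Monte-Carlo runs
of a 5-species, 800-bp, gap-enforced survey (intra target 0.02, inter
target 0.12) for delimitation, gap and monophyly recovery; 200 random
50-site pairs for the distance kernel; 100 judgment matrices for the AHP
cross-check. These sizes give stable percentages in seconds while keeping
every replicate fully independent.

## Known limitations

- The ASAP scorer ranks candidates sensibly on separable data but is not
  the published probability model; absolute scores are not comparable to
  ASAP's asap-scores.
- ABGD's modal-partition tie-break (fewer MOTUs) is conservative and can
  lump when exactly half the priors split.
- The identification module performs exhaustive global alignment — fine at
  survey scale (hundreds of references), not built for genome-scale
  libraries.
- K2P saturation is flagged, not corrected; heavily saturated datasets
  should use richer models outside this package's scope.
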
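# Methods

## Scope and data model

The package operates on genus-level sample × taxon abundance tables for
three kingdoms (bacteria, fungi, nematodes), a genus-level nematode trait
table, and a sample metadata table (treatment, replicate). All indices are
computed per sample; treatment-level summaries are means of per-sample
values. Hypothesis testing between treatments (ANOVA/LSD lettering) is
deliberately out of scope, as are raw-read processing, OTU clustering,
ordination and structural-equation modeling.

## Trait reference

Faunal analysis requires three genus-level traits: trophic group (BF
bacterivore, FF fungivore, PP plant parasite, OP omnivore-predator), the
colonizer–persister class cp ∈ {1..5}, and mean individual fresh body mass
W (µg). The packaged table covers 30 common soil genera and was compiled
by the package authors from the public Nemaplex trait compendium (feeding
classifications after Yeates et al. 1993, c-p after Bongers 1990); fresh
weights are genus-level means and are the weakest link in any footprint
computed from them — different compendium snapshots differ by factors of
2–3 for some genera. The file is plain TSV and user-replaceable; nothing
in the code assumes the packaged values.

OP genera are coded `Om` in guild notation unless a per-genus `op_code`
column marks them carnivores (`Ca`). All index weightings treat Om and Ca
of the same c-p class identically, so the default is harmless; the
distinction is kept because downstream users may want it for display.

Genus matching is exact after trimming and case-folding — no fuzzy
matching, because a silent mis-assignment is worse than a logged miss.
Unmatched genera are excluded from index math and reported, never imputed.

## Diversity

Chao1 uses the bias-corrected singleton/doubleton form
S_obs + n₁(n₁−1)/(2(n₂+1)) and refuses non-integer counts (singletons are
undefined on proportions). Shannon uses natural log. Indices are computed
on the table as given — no rarefaction; if a user wants indices on
rarefied counts they should rarefy upstream.

## Faunal indices

The guild-weighting scheme follows the canonical Ferris et al. (2001)
parameterization: enrichment weights Ba1 → 3.2, Fu2 → 0.8; basal weights
Ba2, Fu2 → 0.8; structure weights 1.8/3.2/5.0 for free-living c-p 3/4/5 of
any feeding group. Plant parasites never enter e/b/s. The weights are
configuration (`FaunalWeights`, YAML-overridable), not constants, so
alternative parameterizations can be matched exactly.

Design choices where the literature is not uniform:

* **TD** is defined as reciprocal Simpson dominance over the four
  trophic-group proportions (1 = single group, 4 = even); outputs should
  be read with that definition in mind.
* **MI** includes c-p 1 opportunists by default (`include_cp1=False`
  switches to the tradition that excludes them).
* **Quadrants**: A (EI≥50, SI<50), B (both ≥50), C (EI<50, SI≥50),
  D (both <50); the boundary value 50 counts as "high".
* **Undefined values** (zero denominators — e.g. no free-living taxa) are
  emitted as NA, never as 0: BI = 100 and "EI undefined" are different
  ecological statements.

## Metabolic footprints

Per-taxon footprint F = N·(0.1·W/m + 0.273·W^0.75): the first term
approximates carbon bound in production (biomass over lifespan, with c-p
class as the lifespan proxy), the second respiration scaling with
metabolic body mass. Group footprints are sums over trophic-group members;
Fe sums over the enrichment-opportunist guilds (Ba1, Fu2) and Fs over
free-living c-p 3–5 taxa, following the Ferris (2010) guild families
(enrichment = fast responders to resource pulses, structure = higher
trophic levels with regulatory roles).

Footprints are linear in abundance, so they require *absolute* counts;
`group_footprints` refuses to run unless the caller asserts
`absolute_counts=True`. Amplicon read counts are not individual counts —
treating them as such is a common but lossy convention, and the flag
forces that decision to be explicit rather than silent.

The functional-footprint rhombus is centered at (SI, EI) with horizontal
diagonal Fs/k and vertical diagonal Fe/k; area = Fe·Fs/(2k²). The display
constant k has no canonical definition; the package defaults to
k = max(Fe, Fs)/50 per dataset (largest diamond spans the 0–100 plane) and
always reports the k used, since areas are only comparable at equal k.

## Energy-flow ternary frame

The reference triangle has base (0,0)–(100,0) and apex (50, 86.6); 86.6
is 100·sin 60° at the conventional one-decimal precision, and the printed
frame is used consistently so barycentric round-trips are exact within it.
Channel fractions divide BFMF/FFMF/PPMF by their three-channel sum; OPMF
is excluded because omnivore-predators integrate over channels rather than
indicating one. (An option to fold OPMF into the channels proportionally
was considered and dropped: proportional folding rescales all three
footprints equally and leaves the fractions — hence the plotted point —
unchanged.) Vertex assignment (bacterial → lower-left, fungal →
lower-right, plant → apex) is a documented configuration of
`EnergyTriangle`, not an assumption baked into the math. A sample with all
three channel footprints zero has no defined point and is reported
missing.

## Co-occurrence networks

Genera are prevalence-filtered (nonzero in ≥3 samples by default, with an
optional detection threshold), tables are joined on shared sample IDs,
and every unordered taxon pair — within and between kingdoms — is scored
by Spearman rank correlation (mid-rank ties, Pearson on ranks). An edge is
retained iff |ρ| > 0.6 and p < 0.05; the sign is the sign of ρ.

p-value methods:

* `t_approx` (default): the ρ→t transform against t(n−2), the behavior of
  most correlation tools. At the replication levels typical of field
  trials (n = 3 per treatment) only |ρ| = 1 can clear p < 0.05, and only
  under this approximation — permutation-exact p-values at n = 3 bottom
  out at 1/3.
* `exact_smalln`: permutation p-values — full n! enumeration for n ≤ 8;
  for larger n, 4,999 seeded Monte-Carlo permutations with the add-one
  correction (valid and slightly conservative).

No multiple-testing correction is applied by default (matching common
practice for these descriptive networks); a Benjamini–Hochberg option is
available. Network summary counts include only nodes incident to at least
one edge, and average degree is defined as 2·links/nodes. Published
network tables sometimes report average degrees inconsistent with their
own node/link counts under this definition (layout software may average
over a different node set); this package defines the quantity explicitly
rather than reverse-engineering any particular tool.

## Synthetic-data generator

The generator emulates the statistical shape of a small phosphorus-rate
field trial: 4 treatments × 3 replicates, genus-level counts for three
kingdoms, mean library size 20,000 counts/sample, negative-binomial
overdispersion 0.3 (variance μ + 0.3μ² — typical for amplicon counts).
Microbial base compositions follow power-law rank-abundance curves (120
bacterial, 80 fungal genera by default). Nematode composition is specified
per treatment over five guild blocks (Ba1, Ba2, Fu2, PP, OP) drawn from
the packaged trait table, split within blocks by a fixed rank-abundance
curve; the few structural bacterivore/fungivore genera (c-p 3–4 Ba/Fu)
are excluded from the simulated pool so block shares map exactly onto the
index formulas.

Latent factors plant monotone associations: each member taxon's log-mean
gains σ·(√ρ·z + √(1−ρ)·ε) − σ²/2, with z shared per sample. Member
log-intensities then correlate at exactly ρ, and the −σ²/2 term keeps
expected library sizes at their configured value. Factor members are
drawn log-normal–Poisson (the factor multiplier *is* their
overdispersion); stacking the independent gamma stage on top would
double-count dispersion and attenuate the planted correlation below its
nominal ρ. Default σ = 2.0 makes the planted biological signal dominate
counting noise at realistic library sizes.

The gradient scenario sweeps Fu2 shares down (0.40 → 0.10) and Ba1 shares
up (0.04 → 0.32) across treatments — fungal-channel dominance giving way
to bacterial — and records its ground truth: the closed-form CI per
treatment and the channel fractions of the noise-free expected tables.
Schedules must be monotone in those directions or entirely flat (null
simulations).

What the generator does *not* emulate: compositional coupling from fixed
sequencing depth, taxon-specific amplification bias, zero-inflation beyond
what the NB tail produces, phylogenetic correlation among taxa, and
spatial/plot autocorrelation. Passing tests therefore demonstrate the
correctness and statistical behavior of the estimators under a clean
generative model, not robustness to every artifact of real amplicon data.

## Numerical conventions

* Undefined indices propagate as NaN and serialize as `NA`.
* Spearman ρ is clipped to [−1, 1] before thresholding; |ρ| = 1 maps to
  p = 0 under `t_approx`.
* Permutation p-values compare |ρ_null| ≥ |ρ_obs| − 10⁻¹² to make ties at
  the observed value count as exceedances.
* Chao1 on a sample with non-integer counts yields NA in the table API
  (and an error in the scalar API).
* All simulation randomness flows from a single `numpy` generator seeded
  by the config (or an explicit override); reruns are bit-identical.

## Problem sizes used in the test suite

Formula-agreement oracles run on 1,000 random communities; geometric
identities on 1,000 random diamonds/simplex points; planted-edge recovery
on 200 simulations of 12 samples × 10 taxa; the false-positive bound on
30 simulations of 12 samples × 20 taxa (5,700 null pairs); the end-to-end
gradient recovery on 100 seeds of the 12-sample scenario. These sizes give
the stochastic assertions comfortable margins (≥3 SE) while keeping the
suite fast.

## Known limitations

* Footprint magnitudes inherit the uncertainty of compendium fresh
  weights; compare footprints only within a consistent trait table.
* Read counts treated as individual counts shift footprint scale by the
  (unknown) reads-per-individual factor; within-study comparisons survive
  this, absolute carbon-flux interpretations do not.
* Spearman networks on compositional data can reflect closure effects;
  compositionality-aware methods (e.g. SparCC) are intentionally not
  implemented here.
* BIOM-format input is not supported; tables are TSV/CSV.
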
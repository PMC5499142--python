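# Methods

This note documents the models behind `scafmap`, the defaults of the
synthetic-data generator (which define the package's study conditions),
and the numerical and design choices made where the procedure left room.

## Two-point linkage model

The cross is an outbred F1 design: two heterozygous parents, no inbred
phase information. Markers are typed by which parent is heterozygous —
D1.10 (parent A only), D2.15 (parent B only), B3.7 (both) — and only these
three classes enter rf estimation. Null-allele classes (C.8, B1.5, B2.6)
are diagnosed by a chi-square goodness of fit of offspring ratios against
the null-allele expectation (2:1:1 for a single null parent, 3:1
called-to-dropout for a double null) at α = 0.05, and only when an
offspring class impossible under the called parental genotypes is
observed; they are excluded from linkage estimation, as they are rare
(about 1% in data of this kind) and their likelihood machinery would
complicate the three dominant classes for little gain.

For marker pairs informative in the same single parent (D–D same parent,
and D–B3.7 restricted to offspring homozygous at the B3.7 marker, whose
transmitted allele is then unambiguous), each informative meiosis is
directly observed as recombinant or parental, up to the unknown phase.
With k mismatches in n informative meioses, the maximum-likelihood
estimate under the better of the two phases is r̂f = min(k, n−k)/n and

    LOD = n log10 2 + k log10 r̂f + (n − k) log10(1 − r̂f).

B3.7 × B3.7 pairs observe the 3 × 3 offspring genotype table; the double
heterozygote class is a mixture of two parental and two recombinant gamete
pairs. The likelihood is maximised by EM over the expected recombinant
gamete count, separately for the four phase configurations (each parent
coupling or repulsion), and the best configuration is reported. The EM is
run to |Δr| < 1e-10 (at most 300 iterations) from r₀ = 0.25, with r
clipped to [1e-9, 0.5]; the test suite checks it against a 1e-4-step grid
maximisation to |Δrf| ≤ 1e-3. D1.10 × D2.15 pairs share no informative
meioses and are reported as non-estimable rather than raising.

## Grouping and the recombination-fraction ceiling

Markers are grouped by single-linkage transitive closure over pairs with
LOD ≥ 3.4. A LOD threshold alone is not a workable grouping criterion at
this design size: LOD ≥ 3.4 corresponds to a per-pair false-linkage
probability of roughly 1e-4 (for fully informative pairs at n = 94,
2·P(Bin(94, ½) ≤ 28) ≈ 1.1e-4), and any marker set dense enough to connect
18 chromosomes contains far more than 10⁴ cross-chromosome pairs, so
single linkage would almost surely fuse chromosomes. Grouping therefore
also caps the estimated recombination fraction of a qualifying edge, which
is standard linkage-mapping practice. The ceiling is class-specific,
because the classes differ sharply in informative meioses and hence in the
width of their null r̂f distributions:

* 0.15 for same-parent D–D pairs (n ≈ 77 after missingness; false-edge
  tail ~1e-10 per pair);
* 0.10 for B3.7 × B3.7 (the EM null, measured on simulated independent
  tables, concentrates above r̂f ≈ 0.14 when LOD ≥ 3.4);
* 0.08 for mixed D–B3.7 pairs, whose informative meioses are roughly
  halved (n ≈ 30–40) and whose binomial tails are correspondingly fatter.

True adjacent markers at the default density sit at rf ≈ 0.01–0.05, far
below every ceiling, so connectivity is unaffected; passing `None`
restores the LOD-only behaviour.

Small groups informative in only one parent are merged into a two-parent
group when they share at least four scaffolds whose relative order
(scaffold position = median marker cM) is identical or fully reversed in
the two maps, iterated to a fixed point.

## Ordering, orientation and conservative distances

Within a group and per parent, markers with identical transmitted-allele
patterns collapse into cosegregation bins. Bins are chained by greedy
nearest neighbour on pairwise r̂f and improved by 2-opt until no adjacent
reversal lowers the total adjacent rf; ties break on (scaffold, position,
marker id). This heuristic is declared, not claimed identical to any
particular multipoint orderer. Haplotype orientation along the chain is
decided by a majority vote over up to eight already-oriented neighbours
(weighted by overlap), which is robust to the occasional adjacent bin pair
with almost no jointly observed offspring.

Distances are conservative event counts: per offspring, the bin-state
sequence is cleaned by discarding maximal single-observation runs
(including terminal ones) as genotyping errors; each remaining state
switch is assigned to the first inter-bin interval of its gap, and the
interval's distance is 100 × events / spanning meioses (no Haldane or
Kosambi transform — intervals are short and the counts deliberately
undercount). A two-bin group therefore has span 0.0 cM: every switch there
is a single-observation run. Whether terminal singletons were discarded in
the original procedure is ambiguous; discarding them is the conservative
reading and is what this package does.

## Composite LD and anchoring

For unphased genotype codes x, y ∈ {0, 1, 2} over pairwise-complete
samples, Burrows' composite disequilibrium is

    Δ_AB = (1/n)[2 n_AABB + n_AABb + n_AaBB + ½ n_AaBb] − 2 p̂_A p̂_B
         = ½ cov(x, y),

and the association statistic is χ² = nΔ²/[(p_A q_A + D_A)(p_B q_B + D_B)]
with D_A = P_AA − p_A² the within-locus Hardy–Weinberg disequilibrium;
r² = χ²/n. The corrected denominator is used because the uncorrected form
(pure allele-frequency products) lets r² exceed 1 under homozygote excess,
contradicting the bounded usage of r²; the uncorrected variant remains
available (`hw_corrected=False`). A minimum pairwise-complete overlap of
20 samples is required (mirroring the ≥ 20-per-class filter scale), and
loci monomorphic within the overlap are undefined and skipped. Thresholds
are applied to |Δ| because allele labelling is arbitrary.

Anchoring is a single pass: an unmapped scaffold joins the LG(s) for which
it has meaningful LD (|Δ| ≥ 0.15 and r² ≥ 0.85, both inclusive) with at
least one variant on each of at least two distinct cross-mapped scaffolds;
one qualifying LG anchors it with weight 1, two split it ½/½, more than
two discard it, and scaffolds with LD only to unmapped scaffolds stay
unanchored. Newly anchored scaffolds never anchor others, so the result is
independent of iteration order.

Perfect-LD blocks are maximal cliques (not components) over scaffolds
whose every pair has at least one witness marker pair with |Δ| ≥ 0.15 and
r² ≥ 1 − 1e-9; overlapping cliques are all reported with their summed
scaffold lengths.

## Map summary conventions

Cross-mapped scaffolds take weight 1 on the draft holding the majority of
their markers; split LD anchors contribute 0.5 to each of their two LGs,
so scaffold totals need not be integers. LGs are renamed by Roman numerals
in descending weighted-megabase order. The reference genome size defaults
to 916 Mb — the cytometric size, not the 899 Mb assembled size, because
the published mapped-fraction percentages (56%, 55.7%) are consistent only
with 916. Map N50 is the size of the LG at which descending cumulative LG
sizes first reach half the genome size (flagged unreached otherwise), and
the genome-wide recombination rate is the mean of the two parental cM
totals divided by the genome size. The core-LG count defaults to the
largest relative gap in the sorted size list (18 on the published table)
and is directly configurable. Reported tables round Mb to 3 decimals and
cM to 1; internal arithmetic is unrounded.

## Probe design choices

Candidate scoring is ordinal lexicographic — uniqueness at the 75%
identity screen, centring of the target polymorphism, few overlapping
heterozygous sites, proximity to the scaffold middle — since only a
preference order is specified; the 75% uniqueness re-check is a ranking
bonus, not a hard filter. Halves/thirds are floor divisions of scaffold
length and a probe belongs to the window containing its start.
"Homozygous sites" counts positions heterozygous in either parent
(including the target itself) against the 100 bp window; counting sites
jointly across both parents is an assumption, flagged here. The
synthesis-attrition step (50,000 → 46,023 probes) is vendor behaviour and
is not modelled. For synthetic genomes, an exact-substring duplication
detector stands in for the alignment-based uniqueness screen; it is part
of the synthetic workflow, and real hit tables in BLAST outfmt-6 are
consumed directly.

## Synteny chance model

The analytic chance expectation for two mapped scaffolds sharing an LG
conditions on the weighted LG size spectrum, Σᵢ nᵢ(nᵢ−1)/[N(N−1)]; the
permutation alternative shuffles the scaffold → LG assignment vectors
across mapped scaffolds (≥ 1000 shuffles) and agrees with the analytic
form within Monte-Carlo error in the tests. Both are reported, since it is
unspecified which the original analysis used. Best hits are lowest
E-value, ties broken by bit score and otherwise dropped, which keeps the
RBH output a partial matching without re-running alignments.

## The synthetic-data generator and its defaults

The generator's defaults are the study conditions for every recovery test
and for `scripts/acceptance.py`; they are a deliberate desk-scale model
(megabase chromosomes instead of ~50 Mb) so the full pipeline runs in
seconds, while keeping the quantities that drive the statistics — 94
informative meioses, 96 panel samples, 18 chromosomes, realistic genetic
lengths — at full scale.

* **Genome**: 18 chromosomes × 1 Mb, 28 scaffolds per chromosome with
  log-normal sizes (σ = 0.9, emulating the skewed assembly), 10%
  repetitive scaffolds. Repetitive scaffolds carry no reliable markers
  (their markers would be duplicated across copies), mirroring why only
  unique scaffolds are mappable.
* **Cross**: 96 offspring at 60 markers/Mb; 40 cM genetic length per
  chromosome, so the total map (~720 cM) matches the published scale
  (746.7/676.4 cM). Crossovers are Haldane: Poisson counts with mean equal
  to the map length in Morgans, uniform on the genetic map, no
  interference — the simplest model consistent with two-point analysis.
  Parental haplotypes draw alleles at Beta(2,2) frequencies, which yields
  the observed mix of segregation classes (roughly 38/38/26%
  D1/D2/B3.7, against 39/38/22 in the real data). Noise: 1% genotype
  errors (Phred 0–20), 5% dropout, 3% low-confidence calls (Phred 3–15),
  which after the cross filter's Phred-15 recode gives ~9% effective
  missingness — the published median — and two planted high-missing
  samples reproduce the 96 → 94 exclusion.
* **LD panel**: 96 samples descended from 2 founder haplotypes through 4
  generations of random mating in a population of 192, 120 markers/Mb,
  0.1% errors, 2% dropout. Two founders and few generations emulate a
  bottlenecked laboratory strain: meaningful LD (r² ≥ 0.85) extends
  ~20–30 kb at these settings (r²(d) ≈ [(1 − r(d))^g]²), spanning a few
  scaffolds — the desk-scale analogue of high-LD strain structure. The
  "anchorable" scaffolds in recovery scoring are those the design gives
  signal for: unmapped unique scaffolds with a retained marker and two
  mapped neighbours with markers within 20 kb, the distance at which the
  decay model predicts r² ≈ 0.94, three sampling standard deviations above
  the 0.85 threshold.
* **Perfect-LD block scenario**: one 12 Mb chromosome in 48 equal 0.25 Mb
  scaffolds, a zero-recombination window at 4–8 Mb, 40 cM/Mb elsewhere, 12
  generations, 30 markers/Mb. The granularity is chosen so that a single
  boundary scaffold joining or dropping from the clique moves the summed
  length by 6.25%, within the 10% recovery band; the dominant residual
  failure modes (a witness marker pair corrupted by a genotyping error;
  allele-frequency drift pushing the window |Δ| under 0.15) have a
  combined probability of a few percent per seed.

What the generator does **not** emulate: sequence-level reads and
alignment artefacts (genotypes are drawn, not called), base-composition
structure (probe-design sequences are uniform random), linked selection or
population structure in the panel (pure drift from a clean bottleneck),
crossover interference, and segregating structural variation. Passing
recovery tests therefore demonstrates that the estimators and decision
rules are implemented correctly and behave as designed under Mendelian and
drift noise — not that they would be equally accurate against artefacts of
a real variant-calling pipeline.

## Degenerate inputs and determinism

Monomorphic loci: HWE p = 1 (no evidence); composite LD undefined and
skipped. Empty maps summarise to zero totals. Single-bin groups have span
0.0 cM. All tie-breaks (pruning scan order, bin representatives, anchoring
and block output order, LG renaming) are lexicographic on (position,
identifier), making every stage deterministic for a fixed seed, and
generator outputs are byte-identical across runs with the same seed.

## Problem sizes

The default pipeline handles ~1000 cross markers × 96 offspring and ~2000
panel markers × 96 samples in a few seconds on one core; all pairwise
screens are exact (no candidate pruning) and vectorised as masked matrix
products, so the cost grows quadratically in marker count and the same
code has headroom for one-to-two orders of magnitude more markers.
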
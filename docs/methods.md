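# Methods

## Screen geometry

The screen models a bacterial cytidine base editor (dCas9–cytidine
deaminase) with a deamination window positioned 16–19 nt upstream of the
first base of an NGG PAM, counted on the protospacer strand and exclusive of
the PAM; equivalently spacer positions 2–5 from the PAM-distal 5' end
(position j and offset o satisfy j = spacer_length − o + 1). Both window
bounds are inclusive and configurable (`EditingWindowSpec`), as are the
spacer length and an IUPAC PAM pattern.

Eligibility is ATG-only. The chemistry argument applies to the antisense
cytosine of the invariant +3 guanine: a sense ATG contains no C, so the
protospacer always lies on the gene's antisense strand, and the
implementation asserts this instead of searching both strands. Genes
starting GTG/TTG (alternative initiators) are reported with reason
`no_ATG_start` rather than silently skipped, so the screen remains
accountable per gene; the other reason codes are `no_geometry_match` and
`overlaps_N` (undefined chemistry on ambiguous bases). Each window offset
yields at most one PAM placement per gene, so a gene has at most
(window span) candidates — four with the defaults.

Coordinates are 0-based half-open on the forward strand internally and
1-based inclusive in GFF3/TSV I/O. For a "−"-strand PAM, `scan_pams` returns
the forward coordinate of the base that is 5'-most in the PAM's own reading
(the forward slice there reads CCN). Window sets falling off a linear genome
are returned empty with an `out_of_bounds` flag; circular genomes wrap, but
topology is explicit and defaults to linear to avoid silent origin-spanning
errors.

### Edit model

Prediction uses deterministic complete conversion: every window C on the
protospacer strand becomes T, which on the gene's sense strand turns the
start-codon G into A (ATG → ATA). This matches the predominant observed
editing outcome; per-position stochastic editing efficiencies are out of
scope. The model is idempotent by construction (C→T leaves no editable base)
and touches only window positions. Window C's other than the target are
annotated as bystanders and classified `five_prime_UTR` / `start_codon` /
`CDS` by forward coordinate against the CDS interval; sense-strand G's in
the window are the same base pairs as antisense C's and are annotated once,
on the protospacer strand, to avoid double counting.

### Panel selection

`select_panel` picks a non-redundant multiplex panel: at most one guide per
gene (the per-gene best under the metric — lower measured escape frequency,
or higher on-target score), then the k best under a lexicographic objective:
smallest sorted metric tuple, then maximal pathway-tag diversity, then
smallest gene-id tuple. Boundary metric ties are resolved by exhaustive
search within the tie group, so the output is deterministic and provably
optimal under the stated ordering. On-target activity scoring is a pluggable
hook returning an opaque number; no scorer ships by default, since activity
prediction is delegated to established external tools.

Cassette assembly concatenates per-spacer transcription units with unique
linkers and rejects any BsaI recognition site (GGTCTC/GAGACC, the two strand
readings) in the assembled product, which would collide with BsaI
restriction–ligation into the sgRNA backbone. Cross-strain portability is an
exact-substring check of protospacer+PAM on either strand.

## Spot-assay quantification

For a scheme with source volume v (ml of original culture represented by a
step-0 spot), pre-dilution d₀ and step ratio r, a count c at step k implies
`CFU/ml = c · d₀ · rᵏ / v`. The built-in schemes encode the two published
plating geometries: induced v = 1 ml, d₀ = 1, r = 5 (range 1.0–3.9 × 10⁵
CFU/ml under the one-colony-at-extreme convention) and non-induced
v = 0.015 ml, d₀ = 100, r = 10 (6.7 × 10³–6.7 × 10¹¹). Their ratio of
extremes gives the escape-frequency detection limit 1.5 × 10⁻¹². The induced
minimum is modeled as exactly 1 CFU/ml; agreement with the printed limit is
at two significant figures.

`estimate_cfu` uses, per replicate, the least-diluted spot inside a fixed
countable band of 1–50 colonies (manual counting has no published band; a
fixed one makes the estimator deterministic), converts it, and averages
replicates. All-zero replicates are censored at the detectable minimum and
never reported as zero; saturated replicates flag `above_range`. The
aggregate is below-detection only when every replicate is. Escape frequency
is the induced/uninduced CFU ratio with censoring propagated, and the NIH
criterion is evaluated inclusively (≤ 10⁻⁸) on the reported value, which for
censored estimates is the detection bound.

Growth fitting slides windows of ≥ 3 points over ln(OD₆₀₀), keeps windows
with r² ≥ 0.99, and takes the maximal slope (ties → earliest window);
doubling time is ln 2 / μ_max, exact by construction. The protocol-free
choices (window length, r² threshold, tie-break) are fixed here because no
fit protocol accompanies the published rates. Significance uses Student's
pooled-variance two-tailed t-test; for escape frequencies a log₁₀ transform
is available, substituting censored zeros with half the detection floor
(minimal convention keeping logs finite, count reported). Two identical
constant groups return t = 0, p = 1 by convention. Stars: * p<.05, ** p<.01,
*** p<.001, **** p<.0001, strict inequalities.

## Synthetic data

### Planted genomes

`generate_genome` writes random background, places non-overlapping genes
(36–75 nt CDS, ≥ 40 nt spacing, both strands) and controls the admissible
PAM band around each start codon: targetable genes get exactly one planted
antisense NGG at a random window offset; non-targetable genes get either a
GTG start or a sanitized band containing no compliant PAM, so they violate
the geometry provably. After construction the full screen is run and
compared to the planted truth; any mismatch from incidental background
geometry triggers regeneration from a derived seed (in practice the
sanitization makes this a no-op). All randomness flows through one seeded
generator, so outputs are byte-identical per seed. These genomes exercise
the geometry exhaustively but are not realistic chromosomes: gene density,
codon usage, and GC content are arbitrary, so passing screens demonstrate
coordinate/strand correctness, not performance on real annotation quirks
(overlapping genes, pseudo-genes, multi-contig assemblies are out of scope).

### Assay simulation

`simulate_assay` draws each spot's colony count Poisson with mean equal to
the exact scheme-algebra expectation for the true CFU/ml (induced truth =
escape × uninduced density). Plating variance beyond Poisson, colony
overlap, and counting error are ignored — the minimal model consistent with
manual counting. Estimator-recovery tests therefore bound only statistical,
not systematic, error.

### Serial-passage simulator

The durability model tracks a population over the 2^L resistance genotypes
of L targeted loci through repeated rounds of: regrowth to carrying density
(default 10⁹ CFU/ml, the observed stable density of uninduced cultures) by
deterministic doubling, with per-locus resistance arising at a per-cell
per-generation rate; one induction pulse in which a cell survives iff every
locus is resistant or escaped editing (per-locus survival (1−eᵢ) + rᵢeᵢ,
loci independent — multiplexing multiplies kill probabilities, the mechanism
of its durability gain); and a 1:1000 bottleneck into the next round
(10 rounds by default). Escape is survivors over the pre-pulse population.
Demographic stochasticity enters only at mutation, editing survival, and the
bottleneck.

The per-pulse editing efficiency per locus and the resistance supply are not
published, so defaults are model choices, fixed once: eᵢ = 0.999 (single-
locus naive escape ~10⁻³ per pulse, the scale at which a one-locus switch
fails the 10⁻⁸ criterion immediately while a three-locus switch starts near
10⁻⁹), and a resistance rate of 10⁻⁸ per locus per generation (order of
magnitude for inactivating point mutations over a ~30 bp PAM/protospacer
target at ~10⁻⁹–10⁻¹⁰ per bp per generation). Resistance is locus-specific
and fully protective (e.g. PAM or seed mutation); cross-locus resistance
needs independent hits. `generations_per_round` (default 30) is an upper
bound on doublings per passage interval; growth stops at carrying density.

Because the bottleneck is applied to pulse survivors, a multiplexed lineage
whose survivors number ~1 cell can go extinct in simulation; empty rounds
record escape 0.0. This is a faithful consequence of the model order
(pulse → dilute) and does not affect the qualitative contrast the simulator
is for: single-locus escape exceeds 10⁻⁸ in every round (and, with nonzero
mutation supply, can climb to ~1 as resistant mutants sweep), while the
three-locus trajectory never exceeds 10⁻⁸ across 10 rounds. No numeric
passage-assay value is claimed; trajectories are qualitative.

## Problem sizes and determinism

Property batteries run at desk scale by choice: PAM-scan equivalence on 200
random 1-kb genomes, generator/screen closure on 50 seeds, estimator
recovery at 200 Poisson replicates per decade over escape 10⁻⁷–10⁻², panel
optimality versus exhaustive search on candidate sets ≤ 12, and passage
product-rule checks at 10⁶–10⁹ cells. Every stochastic test fixes its seeds;
hypothesis-based tests are derandomized.

## Known limitations

Single-contig genomes only; ambiguity codes beyond N are rejected;
genome-wide off-target enumeration, ABE guide design, deaminase kinetics,
and sequence-level modeling of resistant alleles are out of scope. The
reference-genome integration check needs externally supplied inputs (the
4.6 Mb MG1655 FASTA and the essential-gene table) and fails until they are
placed under `data/external/`.
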
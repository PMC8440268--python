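# Methods

## The genetic model

The pipeline targets a single recessive locus (*efl*) segregating in a
bi-parental cross between a mutagenesis-derived early-flowering line
(maternal parent) and a late-flowering wild type. Homozygous-mutant
plants draw their days-to-flowering from an early normal distribution;
heterozygous and homozygous wild-type plants draw from a late one
(heterozygotes are phenotypically late, matching the F1 behaviour of a
recessive allele). No epistasis, no second QTL, no selection during
inbreeding.

### Meiosis and population structure

Crossover counts per chromosome are Poisson with mean equal to map
length in Morgans, positions uniform, no interference (Haldane
assumptions). An F2 is one meiosis from the F1; F6 RILs by single seed
descent are five successive selfing meioses of one lineage. Expected
residual heterozygosity at F6 is (1/2)⁵ = 3.125%, which the simulator
reproduces (property-tested at n = 10⁴). Because the crossover model
has no interference, simulated genomes carry slightly more closely
spaced double crossovers than real meioses; consequences are noted
below.

### Phenotype

Each line has a latent mean ~ N(μ_class, σ_class) — defaults
μ_early = 75 d (σ 2.0), μ_late = 87 d (σ 2.5) — and replicates add
N(0, σ_rep = 1.0) noise (3 replicates by default). These values were
chosen so that replicate means span roughly 71–81 d (early) and
82–93 d (late), the category ranges the study design implies, and so
that a fully informative marker explains R² ≈ 0.85 of the variance of
replicate means — close to the published 81.95%. The between-line SD
is the dominant term; with three replicates the replicate noise adds
only ~0.33 d² to the variance of means.

## Marker panels and QC

SNPs are codominant ({A, H, B}); PAV markers are dominant: a
heterozygote shows the presence allele, so PAVs carry no H calls and
contribute a small amount of pseudo-recombination noise wherever
adjacent PAVs are scored for opposite parents. Genotyping error flips
homozygous calls symmetrically (default 1%, a free parameter — no
published value exists for the platform); missingness is independent
per cell (default 5%). A configurable fraction of markers (default
15%) loses its parental-origin labels; such markers are emitted in a
random column orientation and later mirror-expanded.

QC applies, in order: call rate > 0.5 (strict), homozygous allele
frequency count(A)/(count(A)+count(B)) in [0.2, 0.8] (SNPs only),
1:1 distortion χ² = (a−b)²/(a+b) with P > 10⁻⁵ (homozygous classes
only, since H is recoded missing for mapping; the test excludes
heterozygotes by design and this is configurable), and heterozygosity
≤ 0.15 (SNPs only). A marker failing several rules reports all
reasons. Phasing recodes columns so A is always the maternal allele;
ambiguous markers are duplicated into complementary mirror partners,
of which exactly one lands in a real linkage group (the other forms an
anti-phase cluster that the assembly rules discard).

## Linkage mapping

Pairwise recombination between phased markers uses the observed
discordant fraction R among doubly informative pairs; the meiotic
fraction is recovered with the fully inbred selfing-RIL correction
r = R/(2(1−R)) (inverse of R = 2r/(1+2r)). The F6-exact recursion
differs from the F∞ formula by < 0.2 cM at r ≤ 0.15 and is not
implemented. Linkage groups are single-linkage components of the graph
joining pairs with independence-χ² P ≤ 10⁻¹⁸ AND Kosambi distance
≤ 15 cM (the 15-cM rule is applied at clustering; it could also be
read as an ordering constraint, so the threshold is exposed).

Ordering minimises the summed adjacent discordant-pair counts. Groups
of ≤ 9 markers are solved exactly by enumeration; larger groups refine
two starts — greedy nearest-neighbour and a spectral seriation
(first classical-MDS coordinate of the pairwise distance matrix) —
with 2-opt reversals and window-ripple reinsertions (windows 1–3,
O(1) move deltas), keeping the lower-cost result. The spectral start
was added because nearest-neighbour alone converges to count-optimal
but geometrically scrambled orders on dense groups. Orientation is
anchored by placing the lowest marker id in the first half; ties break
by marker id.

Assembly then drops clusters with ≤ 5 markers, drops groups made only
of mirror markers whose partners placed in larger groups, merges
individuals with ≥ 98% genotype identity into a consensus (agree →
call, disagree → missing), removes individuals above the
missing-call (default 650) or double-crossover (default 28)
thresholds — both defaults chosen near the observed values reported
for the real population and exposed in the API — and assigns
cumulative Kosambi positions from adjacent-pair r̂ (not multipoint
likelihood). Every action is logged in the map's provenance.

**Known limitation — map-length bias.** Adjacent-pair distances on
dense maps are sensitive to genotyping error: at 3 markers/cM a 1%
error rate roughly doubles apparent lengths (the analysis drivers show
this and say so), and count-minimal orders can concentrate
recombination into fewer, longer intervals. With error-free genotypes
the assembled three-chromosome map recovers group count exactly, total
length within ~7% and per-group lengths within ~±20% at n = 185
(200 markers/group); tests assert 15%/25% bands. Multipoint
re-estimation would remove the error bias but is out of scope.

## Interval mapping

Genotype probabilities along each group come from a two-state Markov
chain conditioned on the nearest informative flanking markers; the
switch probability across d cM is the map-function inverse r(d),
expanded to the RIL-observed fraction 2r/(1+2r) by default (the map is
meiotic, the data are inbred lines; the expansion can be disabled).
At each 1-cM grid position the EM fits (μ_A, μ_B, common σ) of the
fixed-weight two-normal mixture to tolerance 10⁻⁶ (≤ 200 iterations;
the log-likelihood is non-decreasing and the fit is flagged if
unconverged). LOD is clipped at 0; R² = 1 − σ̂²_full/σ̂²_null. At a
fully typed marker the EM collapses to two-group ANOVA, giving the
closed-form check LOD = (n/2)·log₁₀(RSS₀/RSS₁) and the identity
LOD = (n/2)·log₁₀(1/(1−R²)) (held to 10⁻⁶/10⁻⁹ in tests).

Permutation thresholds permute the phenotype, record the genome-wide
maximum LOD (EM vectorised across permutations) and return the type-7
empirical (1−α) quantile; the seed is recorded. On simulated null
data with the published map dimensions (23 groups, ~2314 markers,
n = 181, bimodal phenotype) the 95% threshold averages ≈ 3.1–3.2,
slightly above the study's 2.95; the no-interference simulation (more
effective tests per cM) plausibly accounts for the gap. Individuals
with missing phenotype are dropped once for the whole scan rather than
position-wise — with simulated data phenotype missingness is global,
so the two coincide.

The peak report includes the two typed markers flanking the peak
(when the peak sits on a typed marker, the interval spans its two
neighbours), their ANOVA LODs and the cM interval between them.

## Candidate-region simulation and screen

The region generator emulates resequencing over a 267,160-bp window
with 40 ORFs (the designated causal ORF has nine exons and a 1,815-nt
CDS; a printed protein length of 717 aa elsewhere implies 2,151 nt —
the CDS length is configurable and the two are not reconciled).
Background substitution sites arise at 0.05/bp (transitions) and
0.025/bp (transversions); each site's carrier set over the 45
accessions (mutant, wild type, 43-accession panel) is Bernoulli with a
Beta(1, 3) frequency, zero-carrier draws reassigned to one random
accession. These rates were set so the mutant parent carries a few
thousand transitions and ~2,000 survive the wild-type subtraction,
the scale the study reports. Carriers are drawn independently per
site, so the generator has no linkage disequilibrium and CDS
haplotype counts run higher than in a real panel; background variants
inside exons are thinned to 10% (purifying selection), bringing
causal-gene CDS SNP counts to the published order (~12 vs 14). The
causal variant is planted by writing a GCA (Ala) codon at residue 534
of the causal ORF and recording the G→A transition (→ ACA, Thr),
carried by the mutant alone.

The screen keeps transitions ({A,G}/{C,T} as unordered pairs) carried
by the mutant, absent from the wild type and from every panel
accession — uncalled genotypes count as reference (a presence/absence
screen over called variants; flagged for sensitivity analysis) — then
tags ORF overlap (VCF/GFF3 1-based inclusive throughout; minus-strand
CDS offsets computed on the reverse complement) and classifies coding
effects by rebuilding the spliced CDS and translating with the
standard code (synonymous / non-synonymous / nonsense). The planted
variant survives in 100/100 simulated regions, and the count of false
co-survivors matches the closed-form expectation of the carrier model
(property-tested). Per-accession CDS haplotypes and their translated
proteins are deduplicated; unique proteins can never exceed unique
haplotypes.

Conservation is the per-column consensus fraction over non-gap
residues of an ortholog protein alignment (perfect = 1, high ≥ 0.5,
else variable; all-gap columns variable at 0). Motif and domain
residue intervals are configuration inputs, not computed: the defaults
carry the annotated SAM-MTase superfamily domain (residues 503–660)
and an assumed motif-X window (528–540) around the causal residue —
the exact motif bounds are not published, only that residue 534 lies
inside it. A conserved-site hit requires a perfect/high column AND at
least one interval overlap. The NJ tree uses uncorrected identity
distances (gaps excluded from numerator and denominator) with
Biopython's neighbour-joining; negative branch lengths are clamped to
zero with the deficit moved to the sister branch. Promoter alleles are
typed purely by length against the known 1,208/1,423 (Ku)/5,162 (Jul)
bp deletions; a full-length sequence is the wild-type ku allele.

## Co-segregation and expression

Phenotype categories are closed day-ranges on replicate means
(defaults 71–78 / 84–95; values in the gap → missing). The study's
two printed categorisations use different boundaries, so both ranges
are parameters; the statistical-testing variant (71–81 / 82–93)
appears in the analysis driver. Goodness-of-fit χ² supports any
expected ratio, with Yates' correction optional for two classes
(default off; for the published 87:98 counts the uncorrected statistic
is 0.654 and the Yates value 0.5405 — the printed 0.538 matches
neither exactly, and the underlying counts may have differed, so no
exact reproduction is claimed; the printed F2 statistic cannot be
recomputed because its class counts are unpublished). Bulk calls are
the union of alleles carried by the bulk's members. Concordance under
the recessive model requires homozygous-mutant ⇔ early among
individuals informative in both; every discordant line is listed.

Relative expression is 40 − (mean target CT over primer pairs −
reference CT), a log₂ scale on which a group difference Δ is a
2^Δ-fold expression difference. Factor effects (genotype, treatment,
stage — those with ≥ 2 levels) are tested by fixed-effects type-II
ANOVA with Tukey HSD per factor; replicate structure is not modelled
as random (no mixed models, matching the published analysis).

## Problem sizes and randomness

All generators take one integer seed; sub-streams are spawned with
`numpy` `SeedSequence`, so every table, scan and summary is
reproducible byte-for-byte from (config, seed). The test suite runs
the power study at 100 seeds with 100 permutations per seed on a
three-chromosome genome, and the acceptance script estimates the null
threshold from three replicate simulations at the full published map
dimensions with 400 permutations each — sizes chosen so each study
completes in minutes on one CPU while keeping Monte-Carlo error well
inside the asserted bands. Simulated data share the statistical
structure of the real populations but none of their biology: passing
tests demonstrate that the algorithms recover what was planted under
the stated models (no interference, no LD, symmetric error), not that
the pipeline would reach identical numbers on the real genotype data.
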
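# Methods

## The model

`fluxscape` studies how *Escherichia coli* phenotypes distribute on the
rate–yield plane — substrate uptake rate *q* (mmol gDW⁻¹ h⁻¹) against biomass
yield *Y* = μ/(q·m) (gDW per g glucose, *m* the molar mass of glucose) — using
a coarse-grained model of metabolism and protein expression.  The model is a
~30-reaction lumped reconstruction of *E. coli* energy metabolism:
PTS glucose uptake, upper and lower glycolysis with explicit phosphoglycerate
kinase (PGK) and pyruvate kinase (PYK), an oxidative pentose-phosphate lump,
pyruvate dehydrogenase and pyruvate-formate lyase, a TCA cycle with explicit
succinyl-CoA synthetase (SUCOAS), acetate overflow through explicit acetate
kinase (ACKr), the polyphosphate kinases and PRPP synthetase, and an
electron-transport chain (ETC) in which each step has alternative catalysts:
NADH→quinone by either the 13-subunit proton-translocating Nuo complex or the
single-subunit non-translocating Ndh, quinol→O₂ by the high-translocation Cyo,
the lower-translocation Cyd and bd-II (AppBC), or the non-translocating
monooxygenase YgiN, plus a nitrate branch (Nar, Fdn/o, NirAB) that opens only
when nitrate is the electron acceptor.  A single pseudo-metabolite,
"translocated charge", couples ETC translocation to ATP synthase consumption.

Growth maximization is a proteome-allocation problem: every catalyzed flux
*v* occupies the proteome mass fraction *v*·MW/(k_eff·3600·f_fold) and the
ribosome occupies μ/κ_t; their sum is bounded by the budget φ_max.  The
optimal μ is found by bisection (tolerance 10⁻⁶ h⁻¹, at most 60 iterations)
over a linear feasibility program — steady-state mass balance, the proteome
coupling, ATP maintenance (GAM·μ + NGAM), optional growth-rate or
ATP-synthase-fraction equality — and, among alternate optima at μ*, the
solution with minimal total enzyme proteome is returned (HiGHS, deterministic,
feasibility tolerance 10⁻¹⁰; the mass-balance residual is asserted ≤ 10⁻⁸ per
solve).  With the fraction-coupling equality active the feasible growth rates
form an interval that need not contain zero (at μ = 0 there is no NADPH sink,
so the TCA cycle cannot run and high fractions are unreachable); the solver
therefore probes a coarse grid for an interior feasible point before
bisecting the upper edge.

Temperature (25–46 °C) acts only through the equilibrium folded fraction of
each enzyme under a two-state model with a Gibbs–Helmholtz stability curve
ΔG(T) = ΔH_m(1 − T/T_m) − ΔC_p((T_m − T) + T·ln(T/T_m)), anchored so that
ΔG(37 °C) equals the enzyme's reference stability ΔG_ref, with ΔH_m and ΔC_p
scaled from ΔG_ref (150 + 8·ΔG_ref kcal/mol and 1.2 + 0.05·ΔG_ref
kcal/mol/K).  Catalytic rates themselves are temperature-independent;
chaperone-assisted folding is deliberately omitted (spontaneous two-state
folding only).

## The central statistic

For each optimal solution the fraction of total ATP production carried by
each of the eight ATP-producing reactions (ATPS4rpp, PGK, PYK, ACKr, PPKr,
PPK2r, SUCOAS, PRPPS) is computed from the fluxes, counting reversible
reactions only in their producing direction; all eight carry one ATP per unit
flux in this network, so the accounting weights are exactly 1.  The first
element, f_ATPS, indexes the cell's energy strategy: 0 is fully fermentative,
~0.83 is the stoichiometric ceiling reached by full respiration through
Nuo + Cyo.  The coarse PRPPS lump is written r5p → prpp + atp — one
ATP-equivalent credit for the diphosphate transfer — so that its registry
weight equals its stoichiometric ATP coefficient; its flux is tied to the
biomass PRPP demand and contributes < 1% of ATP turnover.

Pinning the fraction at a value *p* uses the linear coupling
(1 − p)·V_ATPS = p·(V_PGK + V_ACKr + V_PYK + V_PPKr + V_PPK2r + V_SUCOAS +
V_PRPPS), written on net fluxes so that futile forward/backward cycling of a
reversible registry reaction cannot distort the realized fraction.

## Calibration

Two free constants are pinned deterministically and the result is shipped as
the default model.  First, the charge consumed by the ATP synthase per ATP is
bisected (within [2, 6]) until the maximal f_ATPS over the stoichiometric
flux polytope — computed with the proteome cap lifted, so it depends only on
the network — equals 0.83; the calibrated value is 2.4738 charge/ATP, which
should be read as an effective lumped-network constant, not a bioenergetic
claim.  Second, the wild-type optimum at 37 °C must lie in the
highest-fraction regime (f_ATPS ≥ 0.6); if it did not, the respiratory
turnover numbers would be scaled up stepwise, though the shipped defaults
already satisfy it (f_ATPS = 0.749, μ = 0.82 h⁻¹, q = 8.2 mmol gDW⁻¹ h⁻¹,
Y = 0.56 gDW/g).  The procedure is a fixed point: calibrating an already
calibrated model changes nothing.

Enzyme molecular weights and subunit counts follow the real complexes
(Nuo 550 kDa/13 subunits, ATP synthase 530 kDa/8, Ndh 47 kDa/1, …).
Turnover numbers are effective constants chosen so that, at 37 °C, full
respiration is the cheapest ATP source per unit proteome with acetate
overflow a close second — the margins are a few percent, so sampled mutations
(k_eff factors in [0.5, 2]) and thermal unfolding flip the optimum between
discrete strategy vertices.  Reference stabilities stagger the ETC:
Cyo (ΔG_ref 2.6 kcal/mol) unfolds first as temperature rises, then Nuo (3.2),
then the synthase (4.2), so the wild-type optimum steps from the fully
respiratory strategy (f_ATPS ≈ 0.75) through intermediate mixtures
(≈ 0.65, ≈ 0.52, ≈ 0.32) to fermentation (0) between 42 and 46 °C.  These
discrete
strategy vertices, jittered by sampled genotypes, are what makes the f_ATPS
histogram multimodal; the exact mode positions are properties of this coarse
calibration, not reproductions of a genome-scale computation.

## Strain sampling

Strains are built in two steps.  (1) Gene selection: one Bernoulli draw per
catalog gene with the gene's mutation probability.  The synthetic
mutation-frequency table draws per-gene counts from a negative-binomial law
(dispersion 0.5 — heavy-tailed, the top decile of genes carries > 40% of
mutations), rescales them by largest-remainder rounding to sum exactly to
266,940 over the 1,566-gene catalog, and converts counts to per-strain
probabilities by dividing by the 1,765-strain panel size (capped at 1), so a
sampled strain carries ~150 mutated genes — the same order as the 10–30%
fixed-fraction sensitivity variants.  (2) Molecular effect: the log of the
k_eff factor is exponential in magnitude (rate 5, truncated at ln 2 and
rescaled linearly for wider variant fold ranges) with an equiprobable sign;
the stability offset is uniform in magnitude up to 2 kcal/mol with the
opposite sign, reflecting the activity–stability tradeoff.  Catalog genes
not represented in the coarse network are phenotypically silent; multiple
mutated genes of one enzyme compose multiplicatively (factors, clipped to the
configured range) and additively (offsets).

Randomness is one `numpy` substream per (temperature, replicate) spawned from
the master seed, so changing one replicate index changes only that strain.
The default survey is 100 strains at each integer temperature 25–46 °C —
2,200 solves, a few minutes on one CPU.

## Landscape statistics

The f_ATPS distribution is fitted as a point mass at zero (values < 0.02,
the fermentative phenotype) plus four Gaussians by EM with 50 deterministic
k-means-seeded restarts (best log-likelihood kept, components sorted by
mean); model preference among 1–5 components uses BIC on the non-zero part.
Aero-types i–v are the zero peak plus the four components in mean order;
assignment is by maximum posterior with ties toward the lower label.  Under
nitrate the same machinery runs with three components (nitro-types i–iii).
Mode separation is reported as the silhouette of the hard assignment.

Phenotypic distance is the Euclidean norm of the 4-vector (q_glc, q_ac, μ, Y)
after component-wise division by the wild-type 37 °C solution — the raw
vector mixes units, so the relative form is used.  Forward stepwise
regression of distance on the eight fractions uses the partial-F criterion
(enter while p < 0.05), skipping rank-deficient additions with a warning.
Proteome complexity counts genes behind enzymes with mass fraction > 10⁻⁶
and the unweighted mean subunit number over expressed enzymes.  Flux PCA
standardizes the central-metabolism flux columns (zero-variance columns
dropped with a warning).  The feasibility envelope regresses Y and q_glc
linearly on f_ATPS per growth-rate isocline and evaluates both lines at
f = 0 and f = 0.83.

## Perturbation experiments

Knockouts remove whole complexes (any subunit gene disables its enzyme, and
operon shorthands like `cyoABCD` are accepted).  The panel reproduces the
eight constructed single/double ETC knockouts; removing every quinol sink
(Cyd, Cyo, AppBC, YgiN) leaves charge without a producer, so the synthase
flux and f_ATPS are exactly 0 under oxygen.  The pinned-fraction experiment
samples at p ∈ {0, 0.37, 0.53, 0.64, 0.71} (24 strains per temperature);
fixed-growth-rate sampling runs at 30 °C at six rates relative to the
wild-type 37 °C optimum {0.18, 0.22, 0.36, 0.44, 0.47, 0.65}, 61 strains per
rate (~366 solves, matching the scale of the original 368-solution set).
The nitrate experiment disables the oxidases, closes oxygen, opens nitrate
(25 strains per temperature, 550 solves); nitrate reduction translocates
2 charge/2e⁻ and the NADH-nitrite reductase NirAB reoxidizes 3 NADH per
nitrite without translocation, which is why the lowest-yield nitro-type —
for which NADH disposal, not ATP, is limiting — expresses it.  Fermentation
pathways stay open under nitrate; the optimizer decides usage.

## Expression statistics

The RNA-seq stage starts from a counts matrix (alignment and counting are
out of scope).  TPM is count/length normalized to 10⁶ per sample and
log₂(TPM+1) is used downstream.  Replicate QC is the squared Pearson
correlation per pair.  Gene selection keeps genes with Pearson p < 0.01
against both acetate production and yield and p ≥ 0.01 against growth rate —
the "not correlated with μ" arm uses the same 0.01 threshold, the minimal
symmetric reading.  Gene-set enrichment is the exact upper-tail binomial
probability P(X ≥ k), X ~ Binomial(n, K/N) with K selected among N profiled
genes; the reported p-value assumes the profiled universe as background.
Sample clustering uses 1 − Pearson distance with average linkage, samples
pre-sorted by id so distance ties resolve deterministically.

## The synthetic expression fixture

The generator emulates the structure the downstream statistics assume, not
any measured data: two aero-type groups of strains receive a bimodal score;
50 planted OXPHOS-like genes (and 20 weaker TCA-like genes) move up with the
score, 30 fermentation genes move down; yield rises and acetate production
falls with the score while growth rate varies independently — so planted
genes correlate with q_ac and Y but not μ.  Each strain is measured in
duplicate (replicate noise 0.04 log₂ units; with 2·10⁶ reads per sample this
gives replicate R² ≈ 0.99) and counts are Poisson draws that invert the TPM
transform.  Because replicates share the biological noise draw, the
selection stage also admits a realistic share of non-planted genes — the
fixture tests recovery of planted signal, not the false-positive rate.
Passing these tests shows the pipeline's statistics behave correctly on data
with known structure; it says nothing about read alignment, library
normalization artifacts, or batch effects in real experiments.

## Problem sizes and numerical choices

The test suite runs the full 2,200-solve survey once and scales the variant
drivers down (pinned-fraction: 4 strains × 8 temperatures × 5 values;
fixed-rate: 15 per rate; nitrate: 6 per temperature); the properties they
check — realized p, correlation signs, mode counts, median orderings — are
scale-free.  Bisection tolerance 10⁻⁶ h⁻¹; LP feasibility 10⁻¹⁰; mixture EM
regularization 10⁻⁸ with 50 restarts at fixed seeds; all sampling flows from
a single master seed per run.  Degenerate cases are defined rather than
guessed: zero total ATP production yields the zero fraction vector with a
degenerate flag, an empty expressed-enzyme set reports (0, 0) complexity,
and yield/P-O ratios raise on non-positive uptake rather than returning
infinities.

## Known limitations

The network is a desk-scale lump: absolute peak positions
(0.75/0.65/0.52/0.32 here) are calibration artifacts and sit at different
values than a
genome-scale reconstruction would give, even though the count of modes, the
rate–yield geometry, the knockout orderings and the nitrate stratification
are reproduced qualitatively.  k_eff is temperature-independent and folding
is two-state without chaperones.  The P/O ratio follows the effective
charge/ATP constant, not measured stoichiometry.  The stepwise-regression
response pools all temperatures.  PPKr/PPK2r are present with a balanced
polyphosphate pool and therefore carry zero net flux in optimal solutions;
their fractions are reported as identically zero.
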
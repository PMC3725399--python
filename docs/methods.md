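# Methods

## Scope and data model

The package analyses per-dose cytogenetic scoring tables with a control
arm. The reference design — the one the packaged fixture and the simulator
defaults encode — scores 500 control cells and 200 cells per irradiated
dose at 0, 0.1, 0.25, 0.5 and 1 Gy of X-rays. Five endpoints are tracked
per dose: chromosome breaks, aberrant cells, stable exchanges, unstable
exchanges and total aberrations (excess fragments + exchanges). A cell is
aberrant iff it carries any structural aberration; when one cell carries
several events it counts once toward aberrant cells and each event counts
once toward its category, so aberrant cells ≤ total aberrations always.

**Break counting.** The break number of a cell is the minimal number of
chromosome breaks necessary and sufficient to produce its aberrations: two
per exchange (stable or unstable), one per excess acentric fragment. On the
packaged fixture this identity reproduces the scored break counts exactly at
0, 0.1, 0.25 and 0.5 Gy (26, 24, 31, 40). At 1 Gy the scored value is 88
while the identity gives 2·29 + 28 = 86; the surplus belongs to complex
aberrations whose composition is not itemised in the source data. The data
model therefore carries an optional per-event `breaks_override` for complex
events, and the fixture stores the scored 88 rather than forcing the
identity.

## Exact and nonparametric tests

`fisher_exact` enumerates the conditional (hypergeometric) distribution in
exact integer arithmetic for tables with total ≤ 2000 (two-sided p = sum of
all tables no more probable than the observed one, the standard minimum-
likelihood convention; one-sided p = tail sum). Larger tables switch to
scipy's hypergeometric with a 1 + 1e-11 relative tolerance on the
probability comparison. `mann_whitney_u` uses midranks for ties; for
combined samples up to 20 observations the p-value is exact by full
enumeration of the C(n+m, n) group assignments, above that a normal
approximation with tie-corrected variance and continuity correction.

## Dose–response models and fitting

Per-cell yields are modelled as

| family | mean function | endpoint use |
|---|---|---|
| linear | c + αD | total aberrations |
| LQ | c + αD + βD² | breaks, stable and unstable exchanges |
| exponential saturation | f_max − (f_max − c)e^(−kD) | aberrant-cell fraction |
| induced-repair LQ | c + [α_r + (α_s − α_r)e^(−D/d_c)]D + βD² | low-dose hypersensitivity alternative |

Constraints: c, α, β ≥ 0; 0 ≤ c ≤ f_max ≤ 1, k > 0; α_s ≥ α_r, d_c > 0.
The induced-repair family reduces exactly to LQ at α_s = α_r; it
transplants the induced-repair idea from cell-survival modelling to a yield
curve, an interpretation rather than a published equation (the source
experiment's own hypersensitivity fits are not printed). With five dose
levels it is saturated (five parameters), which the fit records as a
warning and the F-test refuses ("no uncertainty in the regression").

Count endpoints are fitted by Poisson maximum likelihood on per-dose totals
(k_i ~ Poisson(n_i·Y(D_i))), the aberrant-cell fraction by binomial
likelihood — the standard choices in cytogenetic dosimetry. The fitting
criterion of the source analysis is not stated, so a cells-weighted
least-squares mode on frequencies is exposed as an alternative
(`method="wls"`); on the packaged data the two produce near-identical
fitted curves (individual LQ coefficients trade off on five points and are
not comparable parameter-by-parameter).

Optimisation is bounded L-BFGS-B from several deterministic moment-based
starts (c from the control frequency, α from the low-dose secant, β from
the high-dose residual), followed by a Nelder-Mead polish constrained to
the same feasible set. Covariances are inverse observed information
(central finite-difference Hessian at the optimum, evaluated on the
unconstrained likelihood surface); WLS covariances are Gauss-Markov with
the residual variance on n − p degrees of freedom. Model comparison uses an
extra-deviance F-test with denominator degrees of freedom counted in dose
levels (5), not cells: F = (ΔD/Δp)/(D_full/(n_doses − p_full)). Simulation
under a linear truth at the reference design puts its size near the
nominal 5%.

## Detection thresholds

The detectability criterion formalises "smallest dose producing a
detectable yield": given the observed control row (count c in n_c cells)
and a scoring effort of n cells at the tested dose, k* is the smallest
count whose Fisher exact test against the control row rejects at level α,
restricted to counts above the control rate (without that restriction a
two-sided test can "reject" for a deficit). The minimal detectable yield is
y_detect = k*/n, and the threshold dose D* solves Y(D*) = y_detect on the
fitted (non-hypersensitivity) curve, by bisection on [0, 2] Gy to 1e-6 Gy;
thresholds beyond 1 Gy are flagged as extrapolation beyond the calibrated
range. Note y_detect does not shrink to the control rate as n grows alone:
with the control fixed at 500 cells its own sampling error bounds
detectability near c/n_c + z_α√(p(1−p)/n_c).

Defaults: α = 0.05, one-sided, n = 200 cells. A calibration scan over
α ∈ {0.01, 0.025, 0.05, 0.1}, n ∈ {200, 500} and both sidedness
conventions against the fixture's published threshold row found the default
within 0.03 Gy per point estimate, and the two-sided variant closest of all
(within 0.007 Gy on three of five entries); both conventions are exposed,
one-sided remains the default as the conventional detection-limit choice.

**Upper confidence limit.** The 95% upper CL on D* propagates regression
uncertainty by parametric Monte Carlo: ≥10⁵ parameter vectors drawn from
the multivariate normal (estimates, covariance), truncated to the family's
constraint set by resampling (an error if more than half the draws are
infeasible), the threshold re-solved per draw by vectorised bisection, and
the 95th percentile reported. Draws whose curve never reaches y_detect
within the bracket are kept as +∞ — they cannot shrink the upper limit, so
the CL stays conservative. The procedure is bit-reproducible given the
seed (default 20130729). On the linear family it agrees with the
delta-method closed form to within a fraction of a percent.

**Known limitation.** For the aberrant-cells endpoint the saturating model
on five dose points leaves its rate constant k nearly unidentified
(SE ≈ 1.2 on k ≈ 1.6, corr(f_max, k) ≈ −0.96), so the Monte-Carlo threshold
distribution is heavy-tailed and the 95% upper CL (≈0.5 Gy under the
default criterion) is far wider than the other endpoints' and should be
read as reflecting genuine curve-shape uncertainty, not scoring noise. A
published value computed with a different (unavailable) CI recipe can be
substantially smaller. The point estimate is unaffected.

## Telomere arm

q-FISH telomere length is expressed per telomere as T/C% = 100·T/C against
the chromosome-2 centromere of the same metaphase; the internal reference
makes the measure invariant to staining and exposure gain, which the suite
checks as a property. Groups (dose × harvest time at 24/48 h) are compared
by Mann–Whitney on pooled per-telomere values by default; a per-metaphase-
mean mode is provided because the appropriate unit of analysis is
ambiguous when scoring depth is counted in chromosomes. Dispersion is
reported as the standard error across telomeres. Groups below 1800
chromosomes of scoring depth are flagged with a warning.

## Synthetic data generator

The generator draws, per cell at dose D, a Poisson number of excess
fragments with mean c_f + α_f·D + β_f·D² and a Poisson number of exchanges
with mean c_e + α_e·D + β_e·D²; each exchange is stable with probability
p_stable (default 0.5), unstable subtypes uniform over dicentric/ring/
unbalanced. Only simple aberrations are generated, so breaks =
2·exchanges + fragments holds exactly — complex-aberration surpluses (the
86-vs-88 case above) are deliberately not emulated, nor are break-
rejoining kinetics or multi-generation loss of unstable aberrations.
Defaults anchor the control arm to the reference background (3.6%
fragments, 0.8% exchanges per cell, hence ~4.4% aberrant cells) with
slopes giving a realistic factor ~6 rise over 1 Gy; sample sizes follow
the reference design. Telomere tables draw a log-normal centromere
intensity (median e⁷, σ_log 0.25) and 92 per-telomere T/C% values per
metaphase (46 chromosomes × 2 end-pairs) from a normal with sham mean 33%,
SD 12 T/C points, truncated at zero, with a configurable per-dose shift
(default zero — the null of no radiation effect on telomere length below
1 Gy, which the pipeline reproduces as a property). One integer seed feeds
a root `SeedSequence`; the scoring and telomere streams are spawned from
it, so changing one arm's settings never perturbs the other's draw.

What passing tests on these data do *not* show: robustness to
overdispersion between experiments or slides, scorer variability,
mis-classification of aberration types, or intensity-dependent q-FISH
artefacts — none of which the generator emulates.

## Simulation sizes used in the test suite

Parameter recovery runs 500 replicates of the full reference design
(Wald coverage band 92–98%, relative bias of α below 5%); the F-test size
check runs 300 replicates; the telomere null property uses 12 replicates
× 4 doses × 2 harvest times (96 comparisons at 2300 telomeres per group);
Monte-Carlo upper CLs in tests use 10⁵ draws where a 2% closed-form
comparison is asserted and 2000 draws for smoke-level checks.
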
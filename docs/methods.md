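# Methods

## The stability statistic

The pipeline treats a gene's response to treatment as the vector of
per-replicate log2 ratios

    r_i = log2(T_i + c) − log2(C_i + c),   i = 1..n,

where T_i and C_i are the gene's FPKM values in treated and control
replicate i (paired by column position) and c is a pseudocount. The
response is summarised by the mean Av = mean(r), the sample standard
deviation SD (n−1 denominator), and the coefficient of variation
CV = |SD/Av|. CV is scale-free: multiplying all FPKM by a constant leaves
every ratio, and hence the CV and the ranking, unchanged (exactly in the
c → 0 limit, to high accuracy at expression levels well above c).

The statistic is computed on the ratio scale by default
(`RunConfig.cv_on = "ratios"`). Computing it instead on the treated arm's
per-replicate log2 expression levels is exposed as
`cv_on = "log2_expression"` (via `stability_records_from_matrix`), because
a CV of expression levels rather than of ratios is a meaningful
alternative reading of "stability" when the quantity of interest is the
profile rather than the response; ratios are the default because only the
ratio-scale CV makes the statistic a measure of *response* stability.

**Degenerate means.** When |Av| < ε (default 1e−8) the CV is undefined
(division by a vanishing mean makes it arbitrarily large and sign-unstable).
Such genes are flagged `near_zero_mean`, excluded from rankings with a
logged count, and can never enter a panel. ε is far below any fold-change
threshold of practical interest, so the guard only catches genuine
zero-mean cases.

**Ties.** Ranking is by ascending CV, ties broken by larger |Av| (a
stronger response at equal relative noise is preferable), then by gene
symbol for a fully deterministic order. Records built from the packaged
reference ranking carry no printed Av; they tie-break as |Av| = 0.

## Significance testing

The per-gene treated-vs-control comparison is a two-sided Welch two-sample
t-test on the log2(FPKM + c) values. Welch's form avoids an equal-variance
assumption that six replicates cannot justify. When both arms have zero
variance the p-value is defined as 1.0 for equal means and 0.0 otherwise.
No multiple-testing correction is applied to the per-gene p-values: they
feed a candidate *filter*, not an inference; BH correction is applied only
where families of hypotheses are reported (enrichment Q-values).

## Panel selection

Candidates must satisfy, jointly: p < α (default 0.05), |Av| ≥ fc_threshold
(default 0.585 ≈ 1.5-fold), mean control-arm FPKM ≥ expression_floor
(default 1), and a defined CV. Among candidates with Av > 0 the n_up
lowest-CV genes are selected (default 150), symmetrically for Av < 0
(default 150), and the top_k (default 30) lowest-CV genes of the union
form the high-stability sub-panel. If a direction has fewer qualifying
genes than requested, all of them are returned and the selection carries a
warning flag rather than failing. The fold-change and expression-floor
defaults are package choices (configurable, and stamped into every
output); the panel sizes 150/150/30 mirror the panel structure the
pipeline is designed to produce.

## Reproducibility evaluation

Panel quality is evaluated as the Pearson correlation R between two
replicates' log2 expression profiles restricted to a gene set, with the
standard two-sided p-value from the t-transform t = R·√((n−2)/(1−R²)) with
n−2 degrees of freedom (for a simple linear regression this R is the same
quantity as the fit's correlation coefficient). The nested-set table
computes R between a reference replicate and each other replicate over the
top-s genes of the CV ranking for a ladder of sizes (default
203/174/150/120/90/60/30, clipped to the ranking length), together with
the mean ± SD of the CV within each prefix. On a CV-ascending ranking the
prefix mean of the CV is non-decreasing in s by construction; the
correlations are computed on log2 levels (not ratios) so that the
restricted profiles are directly comparable across replicates.

## Volcano tables

Two plot-ready variants: X = mean log2 ratio in both; Y = −log10 p
(variant `pvalue`) or the gene's CV (variant `cv`). In both variants the
class is `up` iff p < α and X > 0, `down` iff p < α and X < 0, else
`not-significant`; genes without a defined CV appear with NaN Y in the CV
variant rather than being dropped.

## Over-representation analysis

For query list n (a selected panel), gene set K (intersected with the
universe first) and universe N, the p-value is the one-sided
hypergeometric upper tail P(X ≥ k) for the observed overlap k, computed
with `scipy.stats.hypergeom`; Q-values are Benjamini–Hochberg step-up
(`statsmodels.multipletests`); the enrichment ratio is (k/n)/(K/N).
Reporting keeps categories with Q below the FDR threshold (default 0.05),
ascending Q, ties broken by larger enrichment ratio then name, truncated
to the top 10. The default universe is the set of genes passing the
expression floor — an untestably unexpressed gene cannot be a meaningful
background member; it is configurable because annotation-service defaults
differ. Up- and down-panels are tested separately. Only over-representation
(not depletion, not rank-based GSEA) is implemented.

## ER-subtype classification

Evidence per gene: two ERα peak-significance scores (without/with
estradiol, from peaks within ±10 kb of the TSS; treated as opaque ordinal
scores where larger = more significant) and an ERβ S/N ratio
(S = mean of two ChIP replicate signals, N = input signal). Rules:

- ERα-bound ⇔ score(+E2) **strictly** > score(−E2);
- ERβ-bound ⇔ S/N **strictly** > 1.0.

Strictness is forced by the edge cases the rules must reproduce: S/N
exactly 1.0 is a negative ERβ call and 0-vs-0 scores a negative ERα call.
A zero input signal makes S/N undefined; the gene is reported with an
`sn_undefined` flag and a negative ERβ call rather than dropped. The four
classes are ERα (α only), ERβ (β only), ERα/β (both), other (neither).
Peak-to-gene assignment and peak calling are out of scope: the classifier
consumes tabulated evidence. The packaged 29-gene evidence table excludes
the panel's one long non-coding RNA, which has no usable evidence.

## Synthetic data generator

The generator emulates the study design the analysis assumes:

- n_genes (default 26,000 — roughly the assayable human gene complement),
  n_replicates = 6 paired treated/control replicates;
- per gene one control log2-FPKM drawn from Normal(5, 2) (log-normal FPKM;
  the mean and spread put most genes comfortably above the 1-FPKM floor
  and the unit pseudocount) and shared across the control replicates;
- gene classes: stable up-responders and stable down-responders (default
  150 each in 26,000, the panel-sized classes), unstable responders
  (default 1%), remainder non-responders. Class counts are rounded
  fractions of n_genes;
- true effects: |log2 effect| ~ |Normal(2, 0.5)| for responders, signed by
  class (random sign for unstable responders), 0 for non-responders;
- each treated replicate = control + effect + Normal(0, σ_class), with
  σ = 0.1 for stable classes and non-responders and σ = 1.0 for unstable
  responders. A stable responder with effect 2 thus has expected CV near
  0.05 and an unstable one near 0.5, an order-of-magnitude separation the
  ranking should resolve at n = 6.

Noise is additive on the log2 scale because that is the scale the CV
statistic lives on: the ratio noise SD is then exactly σ, making the
planted stability directly controllable. The σ values are chosen for
testability — the real data's dispersions are unknown — so passing
recovery tests demonstrates that the pipeline separates planted stability
classes under this model, not that it would achieve any particular
recovery on laboratory data. Other simplifications: the control arm has
no replicate noise (the spec of the generative model above), no
count-level (negative-binomial) noise, no batch effects, no correlated
genes. A consequence of the constant control arm is that the Welch test
sees one zero-variance arm; the test is well-defined there and the
degenerate-case convention above covers the fully constant case.

Peak evidence is simulated per planted subtype label by drawing scores
that satisfy the corresponding rule (e.g. ERα-positive: q_plus = q_minus
plus a positive increment; ERβ-negative: S/N uniform below 1.0), with
magnitudes spanning the ranges seen in published evidence tables; the
classifier therefore recovers planted labels exactly, which is the
closed-loop property the tests assert. Subtype labels are drawn with
probabilities 0.35/0.07/0.48/0.10 (α/β/both/other), close to the observed
split among published ERGs. Gene sets are simulated with one designated
"responder_module" whose member composition is `enriched_fraction`
responders (filled from non-responders), all other sets uniform draws;
setting `enriched_fraction` to the background responder share yields an
unenriched control set.

All generators take explicit seeds (numpy `default_rng`); identical
configuration and seed reproduce outputs exactly, and no global random
state is touched.

## Problem sizes in the shipped tests

The test suite and worked examples run the generator at 300–2,000 genes
with the responder fractions scaled up to 5%/5%/5% so that planted classes
contain enough genes (100 each at 2,000) for stable recovery statistics;
the selection config is matched with n_up = n_down = 100. The packaged
seed for stochastic assertions is 20220817. These sizes exercise every
code path at desk scale; the defaults remain the full-scale study
conditions.

## Numerical and format choices

- Pseudocount default 1.0 FPKM; log2(FPKM + 1) maps zero expression to 0.
- Exact write/read round-trips: expression matrices are written at 17
  significant digits and parsed with correctly-rounded float conversion.
- Reports are written with a fixed 10-significant-digit float format and a
  `# ergpanel-config: {sorted-key JSON}` stamp (thresholds + seed), which
  is what makes repeated runs byte-identical.
- Gene identifiers are case-preserved and compared exactly; treated and
  control replicates are paired by column position (the only
  reconstructable convention when pairing is not recorded).
- SD of a single-element CV prefix is reported as 0.

## Known limitations

- The pipeline consumes FPKM matrices; read processing and FPKM estimation
  are upstream and out of scope, as are moderated/shrinkage differential
  tests (limma/DESeq-style) — the per-gene Welch test is deliberately
  plain.
- The subtype classifier is exactly as strong as its evidence table; it
  performs no peak calling and no TSS-window assignment itself.
- Correlation-based panel evaluation assumes profiles on a shared log2
  scale; it does not model between-replicate normalisation problems.
- The generator's independence and noise assumptions (above) mean
  synthetic benchmarks bound what the pipeline can do under its own model
  only.
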
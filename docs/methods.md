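# Methods

## Quantification model

The unit of quantification is the average unique-peptide count: for each
protein, the number of distinct peptide sequences identified in one LC-MS
run, averaged over the triplicate runs of one mitochondrial preparation.
This is a spectral-counting-style label-free measure — coarse, but robust,
and the only protein-level quantity available in the curated study tables.
Group 1 is always cytotrophoblast mitochondria (Cyto-Mito), group 2
syncytiotrophoblast mitochondria (Syncytio-Mito); positive log2 fold
changes mean higher in cytotrophoblast.

### Pseudocount ratio and fold change

For counts `c` and `s` the ratio is `R = (c + κ)/(s + κ)` and the fold
change `log2 R`. The default `κ = 1` is the convention that reproduces
every published ratio in the term-placenta differential tables (e.g.
ATP5B: 233/137 = 1.70073, and PCK2's 7-vs-0 maps to exactly 8) and the
third-trimester TPM table. The first-trimester TPM table follows the plain
ratio convention, so the concordance stage carries a per-stage pseudocount:
0 for first trimester, 1 for third. Both are config knobs
(`pseudocount`, `stage_pseudocounts`).

Because a pseudocounted ratio is finite for zero counts, zero-TPM genes
(PC, BCAT2, SLC25A11 in the third-trimester table) go through the same
code path as everything else — no special-casing.

### Direction classes

A ratio is classified `higher_group1` when `R > 1 + t`, `higher_group2`
when `R < 1/(1 + t)`, otherwise `unchanged`; the band is multiplicative so
the classification commutes with swapping group labels. The default
tolerance `t = 0` treats only exact ties as unchanged — with real-valued
averaged counts ties essentially mark equal printed counts. The tolerance
is exposed because a fuller identification universe (hundreds of proteins)
would need a principled band to reproduce an "unchanged" class.

### Fisher's exact test against the background

Each protein's rounded counts are tested with a two-sided Fisher's exact
test on the 2×2 table `[[c, s], [C_tot − c, S_tot − s]]`. The background
totals `C_tot, S_tot` default to the column sums of the rounded counts of
all retained proteins (`background_mode: column_totals`); an explicit
override exists because published per-protein p-values evidently used a
much larger identification universe than the 29 curated proteins, with
totals that were never printed. Consequently p-values computed on the
29-protein fixture are *not* comparable to the published ones (only 7 of
29 reach 0.05 against the small background); ratios, fold changes and
directions are unaffected by the background choice.

The two-sided p-value uses the minimum-likelihood definition: the sum of
hypergeometric point probabilities of all tables with the observed margins
whose probability does not exceed the observed table's. The
implementation enumerates the support with exact integer weights (a
binomial starting weight plus a multiplicative recurrence) and converts to
float once, so tie comparisons are exact — a guarantee float
implementations (including the usual `1 + 1e-7` relative-tolerance rule)
cannot make. `fisher_background_pvalues` computes the whole support of one
margin set in a single sorted-prefix pass; the per-table and batched
routes are tested against each other, against a brute-force
`fractions.Fraction` oracle, and against `scipy.stats.fisher_exact`.

Averaged counts are rounded half-up before testing (the test needs
integers; the curated averages are integers already, so rounding is a
no-op there). If a background column total is zero — possible only in
degenerate inputs where one group has no counts at all — p-values are
reported absent rather than fabricated, with a warning.

### Filters and annotation

Proteins enter the analysis when (1) their gene symbol matches the
mitochondrial inventory (MitoCarta-style list of primary symbols and
synonyms; matching is case- and whitespace-insensitive, synonym hits are
reported under the primary symbol so cross-omics joins are deterministic)
and (2) at least one group shows ≥ 3 unique peptides
(`min_unique_peptides`). The filter applies to the *maximum* across
groups, not both — the retained 7-vs-0 protein (PCK2) forces this reading;
requiring both groups would discard exactly the most extreme, most
interesting proteins.

### Concordance

For each gene present in both the differential results and a per-stage TPM
table, the transcript direction is compared with the protein direction. A
(gene, stage) pair is *concordant* when the directions agree and neither
is unchanged; *conserved across gestation* genes are those concordant at
every stage present (a set intersection, degenerating to the single
stage's set when only one table is supplied). Only signs are compared:
spectral counts on isolated organelles and TPM on whole cells are
incommensurable units, so magnitude agreement would not be meaningful.
Summaries report per-stage matched counts, tested counts and fractions
with explicit denominators.

## Synthetic experiments

`SimulationConfig` defaults were chosen once to emulate the study
conditions and are not tuned per test:

| parameter | default | rationale |
|---|---|---|
| `n_replicates` | 3 | triplicate runs per preparation |
| `depth` | 5000 per group per run | scale of the curated tables' column totals |
| `abundance_log_mean`, `abundance_log_sd` | 2.3, 1.0 | log-normal spread giving per-protein counts from ~0 to a few hundred |
| `de_fraction` | 0.1 | a minority of proteins genuinely differential |
| `fold_changes` | fixed 2.0 | moderate planted effect |
| `de_up_fraction` | 0.64 | the observed ~64:36 up:down direction split |
| `concordance_prob` | 0.875 | the observed ~87.5% proteome–transcriptome agreement |
| `overdispersion` | 0 (Poisson) | no replicate-dispersion information exists to calibrate a negative binomial; a gamma-Poisson knob is provided |

Counts are Poisson per replicate with per-protein rates `λ_i` drawn
log-normal and scaled by `depth / Σλ` — a *common* scale for both groups,
with planted fold changes applied to the group-2 rate afterwards. This
keeps each planted protein's expected count ratio exactly at its nominal
fold change (so truth-recovery checks are well-posed); group 1's expected
run total equals the configured depth exactly, group 2's up to the small
compositional shift the planted effects induce. Group counts are replicate
means, as in the real pipeline. Paired TPM tables give each planted gene
the protein's direction with probability `concordance_prob` (independently
per stage), non-planted genes a random direction, and log-normal
magnitudes. Every stream derives from `(seed, simulation index)` via
numpy's `SeedSequence` mechanism, so runs are bit-reproducible.

What the generator does **not** model: peptide identities and shared
peptides, identification error, between-run correlation, batch effects,
or the compositional coupling of real spectral counts. Passing simulation
tests therefore validates the statistical machinery under its nominal
sampling assumptions, not the behaviour of the procedure on real LC-MS
data.

### Operating characteristics, and a deliberate conservatism

`evaluate_operating_characteristics` runs the full differential stage on
independent simulated experiments and reports type I error (significant
fraction among non-planted proteins), power (significant with correct sign
among planted) and sign-error rate (wrong sign among significant planted
calls), each with binomial standard errors.

A structural finding, reproduced by `analysis/03_operating_characteristics.py`:
testing *replicate-averaged* counts makes Fisher's exact test strongly
conservative. The average of `r` Poisson replicates has variance `λ/r`,
roughly `r`-fold below what the hypergeometric null attributes to a count
of that size, so at the study's triplicate design the empirical type I
error at nominal α = 0.05 is ≈ 5·10⁻⁴ — two orders below nominal — while
power for 8-fold effects at realistic depth still exceeds 80% with an
essentially zero sign-error rate. The acceptance suite contains a
nominal-calibration band test (type I error within 3 binomial SE of α)
that documents this: it fails under the triplicate design, by
construction, and the unit suite instead asserts the defensible one-sided
property that the procedure is never anticonservative. Users who want
nominal calibration should test per-run counts (`n_replicates: 1`) or sum
rather than average replicates.

## Numerical and formatting choices

* Ratios and fold changes are computed from the raw (unrounded) averaged
  counts; only the Fisher stage sees integers.
* Background totals in `column_totals` mode are sums of the per-protein
  rounded counts, keeping `c ≤ C_tot` exact.
* Result TSVs print at ≥ 6 significant figures with enough decimals that
  any magnitude survives a write/read round trip within 1e-5.
* JSON summaries carry full precision and sorted keys; reruns with
  identical inputs are byte-identical (manifest timestamp aside).
* Test tolerances against published values are half a unit in the last
  printed decimal, floored at 1e-5 (several published log2 values were
  evidently computed from already-rounded ratios and differ from
  full-precision recomputation by a few 1e-6). Published TPM *inputs*
  carry ~7 significant figures while some published ratios print more, so
  recomputed expression ratios are compared at a 1e-4 floor.

## Known limitations

* The packaged count table covers only the 29 curated significant
  proteins, not the full ~650-protein identification universe; population
  statistics of that universe (direction totals, published p-values)
  cannot be recomputed from shipped data.
* Unique-peptide counts saturate for long/abundant proteins; no length or
  saturation correction is applied, matching the source analysis.
* The concordance stage treats the two single-cell datasets as given
  average-TPM tables; no reprocessing, batch correction or uncertainty
  propagation on the RNA side.
* Pathway labels come from two static curated maps (table-block headers
  and a nine-category functional variant, the latter leaving the two VDAC
  channels unassigned); no enrichment statistics are computed.
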
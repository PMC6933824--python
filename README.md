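# trophomito

Differential abundance of mitochondrial proteins between the two trophoblast
lineages of the human placenta, quantified by label-free spectral counting,
with cross-validation against single-cell transcriptomes.

As cytotrophoblast cells fuse into the syncytiotrophoblast, their
mitochondria change shape, cristae structure and bioenergetic behaviour.
This package implements the comparative analysis behind that observation:
mitochondria isolated from each lineage (Cyto-Mito and Syncytio-Mito) are
profiled by LC-MS, each protein is quantified as its *average unique-peptide
count* over triplicate runs, and per-protein abundance differences are
tested and then checked for direction agreement with cytotrophoblast vs
syncytiotrophoblast RNA expression in published single-cell data from first-
and third-trimester placenta.

## The statistics

For a protein with averaged unique-peptide counts $c$ (Cyto-Mito) and $s$
(Syncytio-Mito):

* **ratio** $R = (c + \kappa)/(s + \kappa)$ with pseudocount $\kappa = 1$,
  so zero-count proteins stay finite (7 vs 0 gives $R = 8$);
* **fold change** $L = \log_2 R$, positive when the protein is higher in
  cytotrophoblast mitochondria;
* **significance** from a two-sided Fisher's exact test of
  $[[c, s], [C_{tot} - c,\ S_{tot} - s]]$, where $C_{tot}, S_{tot}$ are the
  background column totals of all retained proteins; the p-value is computed
  by exact integer enumeration of the hypergeometric distribution
  (minimum-likelihood two-sided definition), $\alpha = 0.05$, no
  multiplicity correction (optional Benjamini–Hochberg q-values available);
* proteins need $\geq 3$ unique peptides in their better group to be tested,
  and only proteins matching a MitoCarta-style inventory of
  mitochondria-localized gene products enter the analysis;
* **concordance**: for each gene shared with a per-stage TPM table, the
  transcript ratio $(TPM_{cyt} + \kappa)/(TPM_{syn} + \kappa)$ is computed
  (plain ratio, $\kappa = 0$, in the first-trimester table; $\kappa = 1$ in
  the third-trimester one) and a gene is *concordant* when protein and
  transcript move the same way; genes concordant at both stages are
  *conserved across gestation*.

A synthetic-data module simulates the whole design — log-normal protein
abundances, triplicate Poisson counts at configurable sequencing depth,
planted fold changes, paired TPM tables with controllable direction
agreement — and estimates type I error, power and sign-error rate of the
procedure over simulation replicates.

## Worked example

The package ships the curated study tables (counts for the 29 significantly
differential proteins, the mitochondrial inventory, both TPM tables). The
numbered scripts under `analysis/` run the full analysis on them:

```sh
$ python analysis/01_differential_abundance.py
29 proteins tested
direction partition: 24 higher in Cyto-Mito, 0 unchanged, 5 higher in Syncytio-Mito
...
$ python analysis/02_transcriptome_concordance.py
first_trimester: 18 of 18 genes direction-concordant (100.0%)
third_trimester: 21 of 21 genes direction-concordant (100.0%)
distinct concordant genes across stages: 25
conserved across gestation (14): ALDH4A1, ATP5A1, BCAT2, BCKDHA, DLD, GLDC,
HSPA9, HSPD1, NDUFA12, SDHA, SLC25A11, TRAP1, VDAC1, VDAC2
```

That is: of the 29 differential proteins, 24 are more abundant in
cytotrophoblast mitochondria (ATP synthase subunits, pyruvate- and fatty
acid-metabolism enzymes, mitochondrial chaperones) and 5 in
syncytiotrophoblast mitochondria (ER-stress chaperones such as GRP78);
every matched gene agrees in direction with the single-cell RNA data at the
stage where it is tested, and 14 genes agree at both gestational stages.
`analysis/03_operating_characteristics.py` adds the simulation study: at
the study's scale the Fisher test on replicate-averaged counts is strongly
conservative (empirical type I error ≈ 0.0005 at nominal 0.05) yet reaches
83% power for 8-fold effects with no sign errors.

The same stages are available as a CLI
(`trophomito report|differential|concordance|simulate|evaluate`), e.g.:

```sh
trophomito report \
  --counts src/trophomito/data/unique_peptides_term_placenta.tsv \
  --annotation src/trophomito/data/mitocarta_symbols.tsv \
  --expression-first src/trophomito/data/tpm_first_trimester.tsv \
  --expression-third src/trophomito/data/tpm_third_trimester.tsv \
  --config configs/study_tables.yaml --out-dir results/
```

writes `differential.tsv`, `concordance.tsv`, `summary.json` and a run
manifest with input digests.

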
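# metaconcord

Paired primary-tumor/metastasis genomic concordance analysis for breast
cancer cohorts profiled by array-CGH and targeted sequencing.

When a patient relapses, targeted therapy can be chosen from the molecular
profile of the archival primary tumor or from a fresh metastatic biopsy.
How often would the two choices differ? `metaconcord` implements the full
analysis used to answer that question on paired cohorts:

* **Copy number.** Probe-level log2 ratios are segmented by circular
  binary segmentation (best arc by the two-sample *t* statistic,
  permutation acceptance, segments of ≥ 5 consecutive probes; each probe's
  *smoothed* value is its segment mean). States are called with two
  symmetric thresholds: |log2| > 0.5 for gain/loss, |log2| > 1 for
  amplification/deletion. Cohort statistics include the fraction of
  altered probes per sample, per-locus Fisher comparison of alteration
  frequencies between groups, gene-level amplified/non-amplified
  concordance per pair, and a GISTIC-like scan (per-probe G-score
  = Σ samples' excursion beyond threshold, circular-permutation null,
  Benjamini–Hochberg q, regions reported at q < 0.25).
* **Mutations.** Variant calls are filtered at VAF ≥ 0.02, depth ≥ 10 and
  population allele frequency ≤ 1%; a variant is *recurrent* when its
  genomic key appears in ≥ 10 samples of a reference somatic catalog.
  Each call is an *occurrence*; it is *shared* when the identical key is
  called in the partner sample. The concordance rate is shared/total
  occurrences, reported per class (all / recurrent / non-recurrent) and
  per VAF cutoff (0.02, 0.05, 0.10), with a two-sided Fisher exact
  comparison between classes (both odds-ratio estimators reported).
* **Similarity.** Pearson correlation matrices of metastases against
  primaries over all probes (CNA) or all detected variant allele
  fractions (absent variant = 0), best-match assignment, and Ward
  clustering on 1 − r distances with multiscale-bootstrap AU/BP support
  per clade (probit(BP_r) regressed on (√r, 1/√r); AU = 1 − Φ(v − c)).
* **Therapy selection.** A rule engine over molecular profiles
  (amplifications, hotspot activating mutations, biallelic tumor
  suppressor inactivation) with two packaged trial panels — a seven-drug
  panel (`shiva_like`) and a five-drug panel (`most_like`) — and
  per-patient primary-vs-metastasis agreement of the selected drug sets.
* **Synthetic cohorts.** A generator with explicit clonal structure
  (truncal events shared by both members, private events per branch,
  ~300× depth, purity ≥ 50%) so every statistic can be validated against
  ground truth; expected occurrence concordance has the closed form
  2q/(1+q) for truncal probability q.

## Worked example

The packaged 23-patient fixture aggregates to the published concordance
table and runs through the same code path as any cohort:

```python
from metaconcord import datasets, variant_analysis as va

catalog = datasets.load_recurrence_catalog()
pairs, tables = datasets.concordance_fixture_cohort()
for cls in ("all", "recurrent", "non_recurrent"):
    r = va.concordance_summary(tables, pairs, catalog, variant_class=cls,
                               vaf_cutoff=0.02)
    print(f"{cls:>14}: {r.shared_occurrences}/{r.total_occurrences} shared -> {r.percent}%")
```

prints

```
           all: 374/499 shared -> 75%
     recurrent: 36/39 shared -> 92%
 non_recurrent: 338/460 shared -> 73%
```

i.e. 75% of the 499 variant occurrences are found in both members of a
pair, and recurrent (driver) variants are markedly more concordant (92%)
than passengers (73%). The class comparison on the same counts gives

```
recurrent vs passenger: p = 0.0067, OR (cross-product) = 4.33, OR (conditional MLE) = 4.32 [95% CI 1.33-22.33]
```

A full synthetic run, chaining simulation → segmentation → calling →
concordance → clustering → therapy → report:

```bash
metaconcord run --seed 3 --out out/           # report bundle in out/report
metaconcord simulate --seed 1 --out cohort/   # just the synthetic cohort
metaconcord concordance cohort/ --out conc.csv
metaconcord cluster cohort/ --matrix cna --n-boot 100 --out dend.nwk
```

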
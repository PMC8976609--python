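# brcascan

Statistical toolkit for germline *BRCA1/2* case-control cohorts: locating
breast/ovarian **cancer cluster regions** along the coding sequence,
estimating per-mutation **penetrance**, and supporting **founder-mutation
dating**.

Carriers of different *BRCA1/2* deleterious mutations face very different
cancer risks depending on where in the gene their mutation lies and whether
it is a recurrent founder allele. This package implements, as reusable
library code with a thin CLI, the analyses a genetic-epidemiology group runs
on such a cohort:

* **Cluster-region scan.** The CDS of each gene is partitioned into bins
  containing a roughly equal number of deleterious-mutation carriers. For
  each bin the odds ratio of breast cancer and of ovarian cancer (carriers
  in the bin vs gene-wide non-carriers, cancer-free reference) are combined
  into the ratio of odds ratios,

  `ROR = OR_breast / OR_ovarian = (b · O_nc) / (B_nc · o)`,

  which algebraically cancels the reference arm. Woolf 95% CIs and a
  two-sided normal test on ln ROR (Fisher's exact behind a flag) give
  per-bin p-values; per-gene Benjamini–Hochberg adjustment at α = 0.05
  calls an **OCCR** (ovarian cancer cluster region, ROR < 1) or **BCCR**
  (breast cancer cluster region, ROR > 1).

* **Bayes allelic penetrance.** For a recurrent mutation with carrier
  frequency `f_case` among breast-cancer cases and `f_ctrl` among
  cancer-free, family-history-negative controls, against a population
  lifetime risk `K` (default 0.053 for Chinese women),

  `P(cancer | carrier) = f_case·K / (f_case·K + f_ctrl·(1 − K))`,

  reported alongside the 0.35 minimum-expected-penetrance reference, with
  optional family-history stratification.

* **Founder dating support.** Average annual population growth rates from
  historical census records via `X = ((P2 − P1)/P1)^(1/n) − 1`
  (displayed in ‰/yr), best-correlation selection among externally
  estimated mutation ages, STR marker chi-square association and
  core-haplotype sharing summaries, and a per-province carrier summary with
  sample-size masking.

* **Synthetic cohorts.** A seed-deterministic generator produces subject,
  variant and STR tables with the exact statistical structure the scan
  assumes (designed region ROR, founder hotspots, star-genealogy haplotype
  decay), so every stage is testable without any data download.

## Worked example

Simulate a study-scale cohort with an ovarian-leaning region (designed
ROR 0.3 on c.1000–c.2700), then scan *BRCA1* in nine bins:

```sh
brcascan simulate --config sim.yaml --seed 1 --out sim/
brcascan scan --subjects sim/subjects.tsv --variants sim/variants.tsv \
    --gene BRCA1 --n-bins 9 --out scan/
```

with `sim.yaml` containing `region_map: [[1000, 2700, 0.3]]`. Typical
output (`scan/bins.tsv`):

```
 gene  bin  n_carriers region start  end    ror  ci_low  ci_high    p_raw    p_fdr call
BRCA1    1          69            5  577 0.7820  0.4727   1.2936 0.338274 0.736398 none
BRCA1    3          61         1011 2030 0.4502  0.2515   0.8060 0.007237 0.065129 none
BRCA1    9          83         5470 5573 1.1365  0.6952   1.8579 0.609797 0.736398 none
```

(abridged to three of the nine bins). Bin 3, which overlaps the designed
region, shows the depressed ROR
(0.45, CI 0.25–0.81); whether it is *called* an OCCR after FDR adjustment
depends on the seed — at this cohort size a designed ROR of 0.3 is near the
edge of detectability, which is exactly the regime the published study
operated in. The founder-dating commands run on the bundled census records:

```sh
brcascan select-age --records src/brcascan/data/han_population_records.tsv
```

prints

```json
{"chosen_time_point": "2 A.D.", "growth_rate_per_mille": 1.54,
 "estimated_age_years": 2090.0, "years_till_now": 2018,
 "discrepancy_years": 72.0, "calendar": "70 B.C."}
```

i.e. the growth rate drawn from the 2 A.D. census (1.54‰/yr) is the one
whose externally estimated mutation age (2,090 years) best matches its own
elapsed time, placing the founder allele's origin around 70 B.C.

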
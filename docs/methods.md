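# Methods

This note documents the statistical models implemented in `brcascan`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Cluster-region scan

### Binning

The scan needs segments of the coding sequence that each hold a roughly
equal number of deleterious-mutation carriers, so that every bin's odds
ratios rest on comparable information. No canonical algorithm exists for
this; the implemented one is:

1. sort the carrier-position multiset and cut it at its empirical quantiles
   (targets `k·N/n_bins`), cutting only between distinct observed positions
   so that all carriers sharing a founder-hotspot position stay together;
2. make one left-to-right repair pass, moving each internal boundary one
   observed position left or right whenever that reduces the max−min spread
   of bin counts.

`brute_force_bins` does the exhaustive cut-point search and is used as a
test oracle on small instances; the repaired solution is never worse than
the plain quantile cut and never better than the exhaustive optimum. Bin
intervals are reported as `[first observed position, last observed
position]`, so gaps between consecutive bins are expected. Variants are
anchored at their 5′-most affected CDS base (the convention that makes an
8-bp deletion starting at c.5470 open a bin at 5470); intronic boundary
positions carry signed offsets ordered `(base, offset)` lexicographically.
The number of bins is a user parameter; `n_bins_for_target` converts a
carriers-per-bin target (~60 by default) into a bin count. Large
rearrangements are expected to be excluded upstream because they would span
multiple bins.

### The ROR statistic

For a bin, with `b`/`o`/`c` the breast / ovarian / cancer-free carriers in
the bin and `B_nc`/`O_nc`/`C_nc` the gene-wide non-carriers per arm:

* `OR_breast = (b·C_nc)/(B_nc·c)`, `OR_ovarian = (o·C_nc)/(O_nc·c)`;
* `ROR = OR_breast/OR_ovarian = (b·O_nc)/(B_nc·o)` — the cancer-free arm
  cancels exactly, so ROR, its CI and its p-value are computed on the
  reduced 2×2 table and are invariant to the control counts (asserted
  numerically over random tables in the tests).

Numerical choices:

* **Zero cells:** 0.5 added to all four cells of the affected table
  (Haldane–Anscombe), keeping estimate and CI finite. An all-zero table is
  an error, not a number.
* **CI and p:** Woolf (log) 95% interval and a two-sided normal test on
  `ln ROR / SE`, so the interval and the p-value are mutually consistent.
  Fisher's exact test on the reduced table is available behind a flag.
* **Multiplicity:** Benjamini–Hochberg applied per gene (m = that gene's
  bin count), the convention verified exactly against the published
  adjusted-p columns. Adjusted p < 0.05 with ROR < 1 calls an OCCR, with
  ROR > 1 a BCCR.
* **Ambiguous subjects:** subjects with both breast and ovarian primaries
  are excluded from both case arms by default (a flag double-counts them
  instead), since the same subject inflating both ORs is worse than losing
  16-in-7,919 worth of information. Subjects whose deleterious variants
  fall in more than one bin are dropped from the scan with a logged
  warning.

The per-bin raw p-values of the original cohort cannot be recomputed
because per-bin phenotype counts were never published; the package instead
verifies the machinery by exact reproduction of the BH step and by
parameter-recovery experiments on synthetic cohorts (below).

## Bayes allelic penetrance

The estimator inverts case-control carrier frequencies against a population
lifetime risk K:

```
P(disease | carrier) = f_case·K / (f_case·K + f_ctrl·(1−K))
```

This is the standard Bayes inversion with P(carrier) mixed over disease
status by K; it reproduces the expected boundary behaviour — penetrance K
when cases and controls are equally enriched, 1.0 when the mutation is
absent from controls, 0 when absent from cases. Defaults: K = 0.053
(estimated mean lifetime breast-cancer risk among Chinese women, Gail
model); reference line 0.35 (approximate lower bound of published carrier
risks); controls = cancer-free **and** family-history-negative subjects.
No small-sample smoothing is applied by default — the "complete penetrance
(100%)" behaviour at zero control carriers requires the uncorrected
estimator — but a pseudo-count flag exists. Carrier (per-subject)
frequencies are used; an allele-frequency mode is available and gives
identical penetrance for rare heterozygous mutations because the factor of
two cancels. Only breast-cancer penetrance is computed: no ovarian
lifetime-risk baseline is established for this population. Age-dependent
penetrance curves and kin-cohort estimators are out of scope.

In family-history-stratified runs the control arm is the full cancer-free
set, because the FH-negative control subset is empty by construction inside
the FH-positive stratum.

## Founder-mutation dating

### Growth rates

The growth-rate equation is implemented exactly in its source form,

```
X = ((P2 − P1)/P1)^(1/n) − 1,
```

with the **population increase** `P2 − P1` in the numerator, not the ratio
`P2/P1`. Only this form reproduces all seven published per-mille rates from
the historical census records bundled with the package; the conventional
compound form is available behind a `conventional` flag and documented as a
deviation. P2 defaults to 1.4 × 10⁹ (the 2020 population). Rates are
displayed in ‰/yr rounded to two decimals. The bundled 1949 census entry is
stored in millions (541.67 M): the source table prints it under a
"thousand" header, but only the millions reading reproduces its published
6.50‰ rate, so the loader normalizes units explicitly per row.

### Age selection

The external LD-based MCMC age estimator is *consumed, not reimplemented*:
its per-growth-rate age estimates enter as a table column. "Best
correlation" between estimated age n̂ and actual elapsed time n is
interpreted as minimum |n̂ − n| (the source names no metric); ties break
toward smaller n with a log note. Calendar conversion subtracts the age
from the present year (default 2020) and labels non-positive results B.C.,
mapping the boundary case 0 to 1 B.C.; the subtraction itself is not
adjusted for the missing year zero, matching how such dates are reported in
the epidemiological literature (2,090 years before 2020 → "70 B.C.").

### STR association and haplotype sharing

Per marker, a Pearson chi-square (no continuity correction) compares allele
counts — two per typed subject — between carriers and controls; a
monomorphic marker is reported untested. No multiple-testing correction is
applied across the nine panel markers by default, matching per-marker
reporting practice; BH is a flag away. Haplotype phasing is out of scope:
the sharing summary consumes externally phased chromosome vectors and
reports, per marker, the modal carrier allele with its carrier and control
chromosome frequencies, setting a founder-effect flag when carriers beat
controls at ≥ 3 consecutive markers (configurable).

### Geographic summary

Per-province carrier counts with the nested masking rule: sample size < 50
→ dark mask, 50–99 → light, ≥ 100 → none (boundary-exact). Masked
provinces keep their counts — masking is presentational — so per-mutation
provincial counts always sum to the national total. Map rendering is out of
scope; the output is a plotting-ready long-format table.

## Synthetic-data generator

The generator emulates the *statistical* structure the analyses assume, at
the study's scale: three arms of 2,400 breast-cancer, 1,697 ovarian-cancer
and 3,641 cancer-free women; 15% of cases (the pooled case-arm carrier
fraction at that scale) and 2.5% of controls carrying one deleterious
variant; carrier positions drawn from a uniform density over a 5,592-bp CDS
plus founder-hotspot point masses (defaults: 9.5% of carrier mass at
c.5470, 4% at c.981).

The key design choice is how phenotypes and carrier positions are coupled.
Within each arm, a subject's *odds* of being a carrier at position p versus
a non-carrier are proportional to `f(p)` (ovarian and control arms) or
`f(p)·r(p)` (breast arm), where `r(p)` is the designed region tilt. Because
the ROR of an interval is exactly a ratio of such odds, the population ROR
of any interval inside a region equals its designed r with no normalization
error — the property the recovery tests rely on. Both case arms share one
baseline carrier fraction; with unequal baselines the designed r would not
be identifiable as an absolute ROR (a real cohort's gene-wide ROR need not
be 1, but then "r" would only be defined relative to the rest of the gene).
Phenotype assignment is multinomial conditional on position, not a
liability model: sufficient for ROR identifiability, fast at desk scale,
and making no claim about age-at-onset or covariate structure.

The STR generator uses a single-locus star genealogy: every carrier
chromosome descends independently from one ancestral haplotype; over g
generations (default 100 ≈ 2,000 years at ~20 yr/generation) marker j's
ancestral allele survives with probability `(1−c_j)^g` and is otherwise
replaced by a population-frequency draw. Expected ancestral-allele sharing
is therefore `(1−c_j)^g + (1−(1−c_j)^g)·p_j`, checked in closed form by the
tests. Default recombination fractions (0.002–0.035 per meiosis) increase
with distance from the focal locus across the nine-marker, ~5.8-Mbp panel;
population allele frequencies are a fixed truncated-geometric profile over
six repeat-length alleles. This is deliberately simpler than a coalescent
model — no genealogical correlation between carriers, no allele-size
mutation — which is adequate for testing sharing summaries but not for
estimating mutation ages.

What passing tests therefore do and do not show: they demonstrate that the
estimators are correctly implemented and calibrated *under the generative
model* (designed ROR recovered, ~95% CI coverage, null call rate at the BH
level, penetrance estimator unbiased at n = 2,000/arm, sharing decay
matching its closed form). They do not validate robustness to features of
real cohorts the generator omits: population stratification, relatedness,
ascertainment through family history, misclassification of pathogenicity,
or multi-variant carriers.

## Problem sizes used in the test suite

Monte-Carlo checks run at the scale a reviewer can re-run on a laptop: 200
replicate cohorts per condition for ROR CI coverage (designed r ∈ {0.3, 3}
on c.1000–2,700, ~30% of the CDS) and for the null call rate (r = 1,
9-bin scan, one-sided binomial consistency check at the 1% level against
the 0.05 target); 500 replicates of n = 2,000/arm for penetrance recovery
(tolerance 2 Monte-Carlo SEs); 200 replicate STR panels for the sharing
closed form (4 MC SEs per marker, Bonferroni-minded across nine markers).

## Known limitations

* The scan's exposure definition (carrier in bin vs gene-wide non-carrier)
  ignores carriers in other bins rather than using them as a reference;
  with unpublished per-bin counts, neither convention can be checked
  against the original cohort's raw p-values.
* The binning heuristic is not globally optimal (one repair pass); the
  brute-force oracle bounds its behaviour only on small instances.
* The penetrance estimator is a plug-in Bayes inversion: it carries no
  uncertainty interval and inherits small-sample noise in `f_ctrl`
  directly (a mutation seen in zero controls is reported as 100%
  penetrant, faithfully to the method, not to biology).
* Negative or zero historical population growth is outside the growth-rate
  equation's domain and is rejected rather than extrapolated.
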
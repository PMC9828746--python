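# beescreen

Screening-level (tier 1) pollinator risk assessment for foliar spray
applications, with honey bees (*Apis mellifera*) as the surrogate
pollinator. The package covers the full screening workflow for a
chemical — here exercised end-to-end on three trisiloxane polyether
surfactants, spray-tank adjuvants whose risk to bees is assessed with
the same framework used for pesticide active ingredients:

* **Exposure**: caste-resolved dietary doses and direct-spray contact
  doses, in either *default* mode (residue-unit-dose based estimated
  environmental concentrations) or *empirical* mode (measured residues);
* **Use-data cleaning**: interquartile-range outlier fencing,
  order-of-magnitude label-error filtering, and neat-vs-mixture
  application-rate selection for self-reported use registries;
* **Residue post-processing**: matrix grouping, censoring rules
  (LOQ/MDL), and peak extraction from field residue studies;
* **Effects statistics**: trimmed Spearman–Kärber LD50 with 95% CI,
  and no-observed-effect doses via Williams-type sequential testing,
  Cochran–Armitage step-down trend, or Fisher's exact with
  Bonferroni–Holm adjustment, with a monotonicity-based test selector;
* **Risk characterization**: risk quotients screened against the
  regulatory levels of concern (0.4 acute, 1.0 chronic).

## The model

For a food matrix with estimated environmental concentration EEC and a
toxicity endpoint, the tier-1 risk quotients are

```
Acute RQ   = EEC / acute LD50          (LOC 0.4)
Chronic RQ = EEC / chronic NOED        (LOC 1.0)
```

In default mode the concentration in nectar and pollen is
`EEC = RUD × AR`, with the residue unit dose RUD = 110 mg/kg per
lb a.i./acre (the upper-bound tall-grass value of the Kenaga nomogram)
and AR the application rate in lb a.i./acre (1 kg/ha = 0.892179
lb/acre). A caste's dietary dose is the consumption-weighted sum

```
dose (µg/bee/day) = Σ_matrix  C_matrix (mg/day) × conc_matrix (mg/kg) / 1000
```

over its daily intake of nectar, pollen and royal jelly; the reported
adult and larval quotients take the maximum over the in-scope worker
castes (nectar forager: 292 mg nectar + 0.041 mg pollen per day; nurse:
140 + 9.6; 5th-day worker larva: 120 + 3.6). Adults foraging at
application time additionally receive a contact dose of 2.7 µg/bee per
lb a.i./acre.

## Worked example

The package bundles a complete example study (three trisiloxane
surfactants: use-registry maxima, an almond-orchard residue study, and
laboratory toxicity endpoints):

```sh
beescreen assess --mode both --out demo_out
```

which writes `rq.csv`, `rq.json` and `report.md`. The default-mode table
(use-registry rates, RUD-based EECs) reads:

| Exposure | trisiloxane-317 adults | … larvae | trisiloxane-OH adults | … larvae | trisiloxane-acetoxy adults | … larvae |
| --- | --- | --- | --- | --- | --- | --- |
| Acute contact | 0.078 | NA | 0.0097\* | NA | 0.011\* | NA |
| Acute dietary | 0.14 | 0.17\* | 0.12\* | 0.049\* | 0.065\* | 0.083\* |
| Chronic dietary | 0.47 | 0.52 | 0.9 | 0.12 | 0.21 | 0.25 |

and the empirical-mode table (orchard rates, measured residues):

| Exposure | trisiloxane-317 adults | … larvae | trisiloxane-OH adults | … larvae | trisiloxane-acetoxy adults | … larvae |
| --- | --- | --- | --- | --- | --- | --- |
| Acute contact | 0.11 | NA | 0.0092\* | NA | 0.0042\* | NA |
| Acute dietary | 0.0036 | 0.0053\* | 0.0032\* | 0.0015\* | 0.00019\* | 0.00028\* |
| Chronic dietary | 0.012 | 0.016 | 0.025 | 0.0038 | 0.00061 | 0.00086 |

Every quotient is below its level of concern (0.4 acute, 1.0 chronic),
so the report ends with *"no acute or chronic risk indicated"* — at
screening level these materials require no higher-tier assessment. A
`*` marks cells whose endpoint was only bounded from below ("greater
than the highest dose tested"), making the quotient a conservative
upper bound. Contact quotients apply to adults only: larvae are
comb-bound and receive no direct spray (NA).

Other entry points:

```sh
beescreen simulate use-records --seed 3 --out use.csv
beescreen clean use.csv --label-max 2.0          # fence + error filter + rate pick
beescreen simulate dose-response --seed 4 --out dr.csv
beescreen ld50 dr.csv                            # trimmed Spearman–Kärber
beescreen noed dr.csv --method auto              # trend or Fisher–Holm by monotonicity
```

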
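# labelaudit

DNA-barcode authentication of seafood market labels: species assignment
from paired Sanger COI reads, label specificity and standard-name
(misnaming) checks, mislabelling adjudication under multiple
label-to-species definition regimes, and a censoring-aware survival model
that standardises mislabelling rates to species-level resolution.

## The problem

Market surveys that test whether seafood products contain the species their
labels claim face three coupled difficulties:

1. **Molecular identification** — a ~300 bp COI barcode is consensus-called
   from a forward/reverse Sanger pair and matched against reference
   databases whose entries are themselves sometimes misidentified, so hits
   need careful curation (identity/coverage/e-value thresholds plus
   confidence rules on per-species database representation).
2. **Label semantics** — a label like *flake* or *snapper* denotes a set of
   species, and the set depends on the definition regime: a comprehensive
   market-usage table, the stricter official naming standard (AFNS), or
   strict/lenient variants of contested umbrella terms. A product is
   **mislabelled** when the DNA-identified species falls outside its
   label's permitted set; it is **misnamed** when the label's wording is
   not an approved standard name — independent notions.
3. **Censoring** — only products labelled at species level are tested at
   species resolution. A coarse label can hide a species-level mismatch.
   Treating label specificity (higher < family < genus < species, coded
   1–4) as the time axis of a survival problem, correct products are
   right-censored at their label's level and mislabelled products are
   events known to have occurred by that level. A parametric
   accelerated-failure-time model, selected and averaged over all covariate
   subsets by AIC (Akaike weights, 95% confidence set), predicts
   1 − S(4): the mislabelling rate *had every product been assessed at
   species level*.

The package ships a synthetic-survey generator that reproduces the design
of a 672-product national audit (7 states × 96 samples, six seafood
groups, three outlet types, exact 50:50 domestic:imported, four
label-specificity levels, group-specific substitution probabilities, toy
reference sequences, Sanger read pairs, and BLAST-like hit tables), so the
entire pipeline runs and is tested with no downloads.

## Worked example

```python
import pandas as pd
import labelaudit as la
from labelaudit import censored_standardisation as cs
from labelaudit.adjudication import adjudicate_cohort, mislabelling_rates, sensitivity_analysis

ref = la.demo_reference()
design = la.StudyDesign(seed=3)                  # 672-product survey
products, truth = la.generate_products(design)

# assume error-free barcoding for the example
calls = pd.DataFrame({"sample_id": truth.sample_id,
                      "status": "assigned", "species": truth.true_species})
regimes = ("comprehensive", "afns", "strict_flake", "lenient_flake")
adj = adjudicate_cohort(products, calls, ref, regimes)

print(mislabelling_rates(adj, "comprehensive", ("overall",)))
print(sensitivity_analysis(adj).round(1))

obs, _ = cs.encode_censoring(adj)
model = cs.select_and_average(obs, ("seafood_group", "outlet_type", "origin"))
print(cs.predict_incidence(model, obs).round(2))
```

prints (seed 3):

```
          regime  stratum  numerator  denominator  proportion     ci_low    ci_high method
0  comprehensive  overall         87          672   12.946429  10.408194  15.484663   wald

               overall  hoki  prawns  sharks and rays  snapper  squid and cuttlefish  tuna
regime
comprehensive     12.9   1.0     0.8             38.8     26.8                   7.9   6.2
afns              22.6   1.0    14.3             41.8     37.5                  34.9   6.2
strict_flake      13.4   1.0     0.8             41.8     26.8                   7.9   6.2
lenient_flake     12.6   1.0     0.8             36.7     26.8                   7.9   6.2

 level  censored  predicted  ci_low  ci_high
     1     10.42      10.45    4.94    30.57
     2     12.13      12.73    6.08    36.55
     3     11.87      14.24    6.86    40.37
     4     12.95      15.39    7.46    43.21
```

Reading the output: 12.9% of assessable products are mislabelled under the
comprehensive regime. Under the stricter AFNS definitions the same cohort
would be 22.6% mislabelled; redefining only *flake* strictly raises the
overall rate (13.4%) while the lenient flake definition lowers it (12.6%) —
only the shark-and-ray column moves. The incidence curve's last row is the
censoring-standardised estimate: had every product carried a species-level
label, the expected mislabelling rate is 15.4% (95% band 7.5–43.2), above
the raw 12.9% because coarse labels hide species-level mismatches. (The
uplift is modest here because this generator draws substitutions at the
same rate at every specificity level; under a latent coarsening mechanism —
see `cumulative_true_mislabel_prob` — the gap widens substantially.)

A thin CLI mirrors the stages: `labelaudit generate`, `identify`,
`adjudicate`, `standardise`, `lint-tables` (see `--help` on each).

## Layout

| module | contents |
|---|---|
| `labelaudit.synthetic_data` | study design, product/truth generator, toy reference DB, Sanger read simulator, hit tables |
| `labelaudit.barcode_identify` | trimming, reverse complement, Needleman–Wunsch, quality-weighted consensus, hit curation, species assignment |
| `labelaudit.label_reference` | taxonomy + label→species tables, synonym resolution, specificity classification, lint |
| `labelaudit.naming_compliance` | OSA fuzzy matching against the approved-name list, misnaming rates |
| `labelaudit.adjudication` | per-regime mislabelling status, Wald/Goodman intervals, sensitivity analysis, vendor comparison, conservation annotation |
| `labelaudit.censored_standardisation` | PMM price imputation, censoring encoding, AFT fits, AIC model averaging, incidence prediction, ordinal specificity model |

See `docs/methods.md` for the statistical details, defaults, and known
limitations.
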
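# bh3rank

Drug-sensitivity ranking for tumor cohorts from qPCR drug-resistance gene
expression and BH3-profiling apoptotic priming.

Chemotherapy response in oral squamous cell carcinoma (OSCC) varies widely
between patients, and multidrug-resistance (MDR) machinery — ABC efflux
transporters (ABCB1/P-gp, ABCG2/BCRP, ABCC1–5/MRPs) and regulators such as
TP53, STAT5B, LRP1, CDKN1A and CDK2 — is a major driver. `bh3rank`
implements, as a tested and reusable pipeline, an analysis that combines two
pre-treatment readouts to pick the best drug per tumor:

1. **Relative expression** of MDR-linked genes from a qPCR array, via the
   comparative-Ct method: ΔCt against reference gene(s), ΔΔCt against normal
   control samples, RQ = 2^−ΔΔCt.
2. **Apoptotic priming**: BH3 profiling reads mitochondrial depolarization
   (JC-1 fluorescence loss) after drug exposure, normalized per sample so
   that the DMSO solvent control defines 0 % and the FCCP uncoupler defines
   100 %:

   priming(i, j) = 100 · (F̄_DMSO(i) − F̄_j(i)) / (F̄_DMSO(i) − F̄_FCCP(i))

From the tumor × drug priming matrix the pipeline computes, per tumor *i*:

- **BPD** (best priming drug): BPD_i = argmax_j priming(i, j)
- **RD** (response difference): RD(i, j) = priming(i, BPD_i) − priming(i, j)

plus cohort summaries (per-drug mean RD, BPD-conditional RD, BPD
frequencies with fractional tie attribution), gene × drug Pearson
correlation with exact t-based two-tailed significance, quartile-based Ct
sensitivity calls, and classification of tumors as **sensitive / moderately
responsive / resistant** by an explicit composite score with tercile cuts
and, independently, by a from-scratch, fully deterministic PAM (k-medoids,
Kaufman–Rousseeuw BUILD + SWAP) clustering of z-scored Ct and priming
features. Shared statistical primitives (variance F-test, one-way ANOVA,
simple linear regression with R²) live in `bh3rank.stats`.

Because no per-tumor raw data accompanies the original cohort, the package
ships a first-class synthetic-cohort generator (`bh3rank.cohort`) with a
latent per-tumor resistance score, planted response classes and an
invertible plate model, used throughout the test suite for
parameter-recovery checks.

## Worked example

Simulate a 31-tumor cohort and run the full pipeline:

```bash
bh3rank simulate --out demo/cohort --seed 7
bh3rank run --config demo/config.yaml
```

with `demo/config.yaml`:

```yaml
out_dir: demo/out
synthesize:
  n_tumors: 31
  seed: 7
seed: 7
```

This prints (abridged) the cohort report:

```json
{
  "avg_rd": {
    "paclitaxel": 1.0595555153767646,
    "vinblastine": 7.630312858933762,
    "daunorubicin": 7.914380899731001,
    "doxorubicin": 11.197591760072378,
    "vincristine": 11.43557845074655
  },
  "bpd_frequency": {
    "paclitaxel": 0.8387096774193549,
    "vinblastine": 0.0967741935483871,
    "daunorubicin": 0.06451612903225806,
    "doxorubicin": 0.0,
    "vincristine": 0.0
  },
  "class_counts": {
    "threshold": {"sensitive": 11, "moderate": 10, "resistant": 10},
    "pam": {"sensitive": 9, "moderate": 17, "resistant": 5}
  },
  "n_tumors": 31
}
```

Reading: under this cohort's generating conditions the taxane analog is the
best priming drug in ~84 % of tumors and its cohort-mean response
difference (1.06 percentage points) is far below every other drug's, i.e.
where another drug wins, it wins narrowly. The two classification routes
(score terciles vs PAM clusters ranked by mean priming) agree on the broad
sensitive/moderate/resistant structure. Full per-tumor tables are written
to `demo/out/` (`expression.csv`, `priming.csv`, `ranking.csv`,
`correlations.csv`, `classification.csv`, `pam.json`, `report.json`); the
same pipeline runs on real data via `ct_path:` / `plate_path:` instead of
`synthesize:`.

Library use mirrors the CLI:

```python
from bh3rank import (CohortParams, generate_cohort, percent_priming,
                     delta_delta_ct, rank_drugs)

cohort = generate_cohort(CohortParams(seed=7))
pm = percent_priming(cohort.plate)
expr = delta_delta_ct(cohort.ct_table)
ranking = rank_drugs(pm.priming)
print(ranking.bpd_frequency.idxmax())   # 'paclitaxel'
```

## Documentation

See `docs/methods.md` for the model, the synthetic-cohort generating
process, numerical conventions and known limitations.
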
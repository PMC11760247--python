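# stratnet

Stratified cross-disorder neural factors from task-based functional
connectomes.

Psychiatric disorders co-occur far more often than chance, and hierarchical
taxonomies of psychopathology explain this with a general factor plus
*stratified* externalizing and internalizing spectra.  `stratnet` is a
Python toolkit for finding the neural side of those spectra in edge-level
functional connectivity (FC): given per-condition connectomes (subjects ×
edges), eight symptom scores split 4/4 into externalizing (ASD, ADHD, CD,
ODD) and internalizing (GAD, depression, eating disorder, specific phobia)
domains, and covariates, it

- computes edge-wise covariate-adjusted brain–behavior associations and
  CPM-style cross-validated brain-predicted symptom scores,
- classifies edges into a mutually exclusive taxonomy — *general* edges
  predicting both domains vs. *stratified* edges predicting ≥ 2 symptoms of
  one domain and none of the other — and tests stratified-edge counts
  against a symptom-shuffling permutation null,
- scores subjects on each factor as summed FC over the factor's edges
  (externalizing = positive-positive stratified edges, internalizing =
  negative-negative stratified edges),
- characterizes factors anatomically via normalized node degree, the
  two-ratio Specificity Score
  `S(F1) = norm(F1)/norm(F2) + norm(F1)/norm(F3)`, predominance, and
  network-pair aggregation,
- analyzes multi-wave data: per-subject OLS decline slopes ("neural
  pruning"), slope–baseline-symptom coupling, and cross-wave symptom
  prediction,
- converts statistics (r ↔ t, one-/two-sample Cohen's d), compares
  case-control groups, and applies fixed edge sets to external task or
  resting-state cohorts.

Because the cohorts this design targets are access-restricted, the package
ships a first-class synthetic cohort generator (`stratnet.simulate`) with
planted, sign-structured cross-disorder edges, correlated symptom domains,
site/sex/age confounding, symptom-coupled longitudinal decline, and
exported ground truth — every stage is testable end-to-end without any
download.  See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from stratnet import SimulationConfig, generate_cohort, SYMPTOMS
from stratnet import brain_behavior as bb, factors

study = generate_cohort(SimulationConfig(seed=1))   # 600 subjects, 60 nodes,
wave1 = study.config.wave_labels[0]                 # 4 task conditions, 3 waves
sym = study.symptoms_at(wave1)
cov = study.covariates_at(wave1)[["site", "sex", "age"]]
conn = {c: study.connectome_at(c, wave1) for c in study.config.conditions}

maps = [bb.edgewise_association(conn[c], sym[s].to_numpy(), cov, alpha=0.05,
                                condition=c, symptom_name=s)
        for c in conn for s in SYMPTOMS]
taxonomy = factors.classify_edges(maps)
ext = factors.split_sign_groups(taxonomy["stop_success"].externalizing)
print(taxonomy["stop_success"].externalizing.n_edges,
      len(ext["pos-pos"].members))
```

prints

```
73 54
```

— in the `stop_success` condition, 73 edges predict ≥ 2 externalizing and 0
internalizing symptoms, and 54 of them carry uniformly positive
associations (the positive-positive sign group that defines the
externalizing factor; 32 of those are planted edges, the ground truth in
`study.truth`).  The
permutation reliability of that count,

```python
res = factors.count_permutation_test(conn, sym, cov, n_perm=199, seed=2)
print(res[("stop_success", "pos-pos")].observed_count,
      res[("stop_success", "pos-pos")].p_perm)
```

```
54 0.005
```

is at the add-one floor for 199 permutations: no symptom-shuffled null
reaches the observed count.

A full pipeline run (simulation → associations → taxonomy → factors →
specificity → longitudinal → summary JSON) is one command:

```sh
stratnet run-all --out out/ --seed 1 --n-perm 200
```

Other subcommands (`simulate`, `assoc`, `factors`, `specificity`,
`longitudinal`, `compare`) operate on the plain-TSV study format; see
`stratnet --help`.

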
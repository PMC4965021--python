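# bodyatlas

SOM-based body typing for anthropometric cohorts.

3D whole-body scanners deliver ~140 body measures (lengths, girths,
angles, weight) per participant in large epidemiological studies. Single
indices such as BMI, WHR, WHtR or ABSI compress that richness into one
number; `bodyatlas` instead stratifies a cohort into multidimensional
*body types* with a two-stage self-organizing-map (SOM) analysis:

1. **Preprocessing** — three ordered missing-value filters (participants
   missing > 50% of measures; measures missing in > 5% of the remaining
   participants; remaining incomplete participants), division of every
   measure by body height (shape, not size), and per-measure
   Z-normalization.
2. **Feature map** — a SOM over the *measures* (items = measure profiles
   across the cohort). Watershed segmentation of its U-matrix groups
   correlated measures into **meta-measures** A, B, C, … (per-participant
   means of the member measures, in Z-units); singleton measures are
   excluded.
3. **Body map** — a second SOM over the *participants* (items =
   row-Z-normalized meta-measure vectors). U-matrix basins holding at
   least 1% of the cohort are **body types**, labelled F*/M*/B* by gender
   composition.
4. **Consensus & stability** — the whole train-and-detect procedure is
   rerun on random sub-cohorts; pairwise co-clustering frequencies give
   intra-/inter-cluster consensus m(k), a single-linkage dendrogram of
   types, and stability curves versus cohort size.
5. **Atlas** — bodygrams (polar meta-measure profiles, Z = 0 polygon =
   cohort reference) and body-map stainings (per-unit means or tertile
   classes of age, BMI, WHtR, WHR, ABSI, or any meta-measure).

Raw scan tables of this kind are access-controlled, so the package ships
a synthetic-cohort generator (`bodyatlas.synthetic`) that reproduces the
structure the analysis assumes — 13 correlated measure blocks + 17 noise
singletons, four gender-linked body-shape components, realistic
height/weight marginals, planted missingness — together with ground-truth
labels for recovery testing. See `docs/methods.md` for the model details
and known limitations.

## Worked example

```python
import bodyatlas as ba

cohort = ba.generate_cohort(ba.CohortConfig(n_participants=2000, seed=1))
clean, report = ba.filter_missing(cohort.to_measure_table())
print(report.to_dict())

normed = ba.z_normalize_columns(ba.height_normalize(clean))

fdata = normed.values.to_numpy(float).T     # measures as items
fsom = ba.train_som(fdata, 30, 30, ba.TrainingSchedule(n_epochs=100), seed=8)
assign = ba.prune_singletons(
    ba.detect_clusters(ba.distance_map(fsom), ba.best_matching_units(fsom, fdata))
)
meta = ba.aggregate_meta_measures(normed, assign)
print(assign.n_clusters, "meta-measures;",
      len(meta.singletons_excluded), "singletons excluded")

types = ba.assign_body_types(ba.z_normalize_rows(meta), grid=(60, 60), seed=9)
ba.label_by_gender(types, normed.covariates["gender"])
print(types.n_types, "body types:", dict(sorted(types.type_names.items())))
```

prints

```
{'n_participants_removed_stage1': 10, 'n_measures_removed_stage2': 6,
 'n_participants_removed_stage3': 280, 'remaining_P': 134,
 'remaining_N': 1710, 'total_missing_cells': 2389}
13 meta-measures; 11 singletons excluded
4 body types: {0: 'F2', 1: 'F1', 2: 'M2', 3: 'M1'}
```

Reading: of the 140 raw measures and 2,000 participants, the filters
drop 10 near-empty participants, 6 badly captured measures and 280
remaining incomplete participants, leaving a complete 1,710 × 134 table.
The feature map groups 123 measures into 13 meta-measures (the 11
leftover singletons are excluded), and the body map resolves 4 body
types — two mostly-female (F1, F2) and two mostly-male (M1, M2),
numbered by descending size — matching the planted structure of the
synthetic cohort.

The same pipeline is scriptable from the shell:

```bash
bodyatlas simulate --seed 1 --n 2000 --out cohort.csv --truth truth.csv
bodyatlas preprocess --in cohort.csv --out clean.csv --report report.json
bodyatlas feature-map --in clean.csv --grid 30x30 --outdir out/
bodyatlas run-all --seed 1 --outdir out/        # end-to-end + manifest.json
```

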
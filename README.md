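# benthomap

Benthic habitat and biotope mapping for Baltic-type shelf seas, as a
tested, reusable pipeline:

- **`benthomap.sediment`** — grain-size classification: simplified Folk
  triangle (Level A/B), Figge sand subdivision (Level C), EUNIS substrate
  categories (mud ≥20 % fines; coarse at >30 % gravel share; sand at >70 %
  sand share; mixed/reef from areal hard cover), and translation of legacy
  soft-bottom map classes.
- **`benthomap.hardbottom`** — boulder point gridding (half-open 50 m
  cells), three density classes (0 / 1–5 / >5 boulders), and the
  hard-substrate rule (>5 boulders, or 1–5 boulders on lag sediment).
- **`benthomap.hub`** — HELCOM HUB code grammar (parse/compose incl. `+`
  unions, `?` wildcards and uncertainty suffixes, the full 84-code legend),
  dominance rules (>50 % biomass for endobenthos; ≥10 % total-area or ≥90 %
  hard-substrate cover for epibenthos), ACFOR cover midpoints, and the
  pre-modelling harmonisation conventions (rare/unpredictable dominants
  removed, poorly separable communities merged).
- **`benthomap.model`** — per-realm random-forest community classifiers:
  70/30 split, OOB-tuned hyperparameters ({250, 500, 1000} trees ×
  ⌊√p⌋±1 predictors per split), imbalance strategies (down-/upsampling,
  balanced weighting, SMOTE) applied to the training partition only, and
  evaluation with overall accuracy, exact binomial 95 % CI, Cohen's kappa
  and mean-pairwise (Hand–Till) multiclass AUC; grid prediction with
  vote-share confidence.
- **`benthomap.composition`** — BHT layer (photic → infralittoral,
  aphotic → circalittoral; <1 ha patches merged into their surroundings),
  HUB layer (epi community wherever hard substrate dominates, codes
  completed with substrate and zone; never generalised), OHT layer
  (reefs/sandbanks carried through as polygons, seagrass at ≥50 %
  occurrence or ≥10 individuals/m², quahog-mud from the HUB code,
  species-rich gravel candidates from indicator stations, reef precedence
  over species-rich areas), and per-class area tables.
- **`benthomap.synthetic`** — seeded synthetic seascapes (gradient + noise
  predictor rasters, patchy sediment, Poisson boulder fields, grab/video
  stations) whose labels follow a known `CommunityRule`, so every stage has
  a recoverable ground truth.
- **`benthomap.io` / `benthomap.cli` / `benthomap.pipeline`** — ESRI ASCII
  grid, CSV, GeoJSON readers/writers with schema validation, and the
  end-to-end orchestration.

## Command line

```sh
# full reference run on a synthetic seascape
benthomap run-all --out runs/demo --seed 1

# individual stages
benthomap simulate --out runs/demo --seed 1 --extent 10000 --cell 1000
benthomap classify-sediment --in samples.csv --out classified.csv
benthomap hardbottom --boulders boulders.csv --sediment sediment.asc --cell 50 --out hb/
benthomap assign-hub --stations stations.csv --out labels.csv
benthomap summarize --layer runs/demo/bht.asc
```

Exit codes: 0 success, 2 schema error, 3 stage failure.

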
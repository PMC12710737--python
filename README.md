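# semcine

Semantic-feature encoding of naturalistic movie fMRI, as a tested,
reusable pipeline:

1. **Segmentation** — sliding-window clip manifest from labeled movie/rest
   run timing (20-s target, 16-s minimum, 10-s step, 5-s terminal buffer).
2. **Responses** — per-run non-rest z-scoring, frame-wise global-mean
   removal, 5-s lagged clip-window averaging; per-tail trimmed group mean.
3. **Encoding** — per-parcel ridge regression (λ = 1 on the standardized
   scale) from 11 clip-level semantic scores in [0, 1], leave-one-out
   cross-validated with fold-internal standardization; R² maps,
   coefficient maps, mean and R²-weighted |β| feature importance, and a
   clip-shuffled empirical null.
4. **Connectivity** — resting-state Fisher-z FC and nodewise strength
   (negative edges clipped to 0, diagonal excluded).
5. **PLS** — SVD of the cross-block covariance between subject × parcel
   encoding-R² and FC-strength matrices, with row-permutation p-values for
   the singular values and sign-aligned bootstrap stability (z) maps.
6. **Cognition coupling** — cross-subject Spearman maps against 7
   age-adjusted cognitive scores with Benjamini–Hochberg FDR over the
   pooled p vector, plus pairwise rho-map similarity.

Because the source neuroimaging data are restricted-access, the package
ships a first-class synthetic-data module (`semcine.synth`) that plants
known structure — a block-sparse parcel × feature weight matrix, a subject
gain coupled to encoding R², a rank-one resting-connectivity axis, and
cognition readouts — so that every stage is verified by parameter
recovery. All generators are pure functions of (config, seed).

## CLI

```bash
semcine simulate --out-dir data/ --seed 1 --n-subjects 24
semcine segment  --timing data/timing.csv --out manifest.csv
semcine extract  --manifest manifest.csv --timing data/timing.csv \
                 --data-dir data/movie --out responses/
semcine encode   --features data/features.csv \
                 --responses responses/group_responses.tsv \
                 --per-subject responses/ --out encoding/
semcine fc       --data-dir data/rest --out fc_strength.tsv
semcine pls      --x encoding/subject_r2.tsv --y fc_strength.tsv --out pls/
semcine cognition --x encoding/subject_r2.tsv --scores data/cognition.csv \
                 --q 0.05 --out cognition/
semcine run-all  --out-dir run/ --seed 1      # everything above, end to end
```

All commands accept `--config cfg.yaml` (YAML with any `PipelineConfig`
field; flags override). Outputs are plain CSV/TSV with a provenance
comment line (config hash + seed); parcel time series can also be stored
as compressed `.npz`. Two runs with identical config and seed produce
bitwise-identical outputs.

`PipelineConfig` holds every constant: TR, hemodynamic lag, the
segmentation constants, ridge λ, trim fraction, permutation/bootstrap
counts, and FDR q.

Neuroimaging-format I/O (CIFTI/NIfTI) is deliberately out of scope:
export parcel-averaged matrices externally (e.g. `wb_command
-cifti-parcellate` + `-cifti-convert -to-text`) and feed the parcels × TRs
text matrix to `semcine.io.read_parcel_timeseries`.

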
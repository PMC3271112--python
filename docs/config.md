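# Pipeline configuration schema

`hemorph run --config config.json` accepts a JSON object with these keys
(defaults in parentheses; see `hemorph.pipeline.PipelineConfig`):

```jsonc
{
  "input_images": ["P01-T0.tif", "P01-T1.tif", "P02-T0.tif"],  // required
  "reference_image": "reference.tif",                          // required
  "output_dir": "out",                                         // required
  "clinical_csv": "clinical.csv",      // optional; enables survival stage
  "block_size": 1024,                  // >= 64
  "margin": 50,                        // overlap context, < block_size/2
  "bins": 10,                          // equal-population bins per feature
  "features": ["area", "cellularity"], // subtyping feature list
  "k_min": 2,                          // candidate subtype range
  "k_max": 8,
  "resamples": 100,                    // consensus resamples per K
  "subsample_fraction": 0.8,
  "seed": 0,                           // all stochastic stages derive from it
  "stain_basis": null,                 // 3x3 array, columns = hematoxylin,
                                       // eosin, residual OD unit vectors;
                                       // null = built-in H&E basis
  "segmentation": {                    // all optional
    "min_area": 40,
    "max_area": 5000,
    "gmm_max_components": 3,
    "gmm_min_pixels": 100,
    "gmm_separation": 2.0,
    "solidity_threshold": 0.96,
    "concavity_depth_min": 2.0,
    "seed": 0
  }
}
```

Tissue ids are the image file stems; a stem of the form `<patient>-T<k>`
assigns the section to `<patient>`, so multiple sections per patient are
averaged at the normalization stage.

`clinical_csv` columns: `patient_id, time_months, event, treatment_group`
with `event` 1 = death observed / 0 = censored and `treatment_group` one of
`more-intensive`, `less-intensive`.

Outputs written to `output_dir`: `mask_<tissue>.tif` (16-bit label masks),
`features_<tissue>.csv`, `global_bins.json`, `distributions.csv`,
`subtypes.csv`, `consensus.csv`, `survival.csv` (if clinical data given)
and `manifest.json` (software version, config hash, seed, selected K).
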
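# File formats

All coordinates are patient-frame millimetres (x toward patient left,
y anterior, z superior), 0-based voxel indexing, half-open bounds.
Tabular headers carry units (`*_mm`, `*_gy`).

## Volumes (`.mha`, `.nii.gz`)

Written via SimpleITK with array axis order (x, y, z), spacing and
origin preserved; round trips are lossless.

## Projection images (`.tiff`, `.png`)

* 32-bit float TIFF (lossless), pixel spacing in the shaped metadata.
* 16-bit PNG: linear quantisation between the stored `vmin`/`vmax`
  text-chunk values; `pixel_spacing_mm` also stored as a text chunk.

## Cohort directory

```
cohort/
  cohort.yaml                 # CohortSpec + geometry
  truth.csv                   # patient,fraction,image,x_mm,y_mm,z_mm
  patientNN/
    phantom.yaml              # full PhantomConfig (reproducible anatomy)
    drr_A.tiff  drr_B.tiff
    fractions/fMM/img_NNNN_A.tiff, img_NNNN_B.tiff
```

## Tables

* `tracking.csv`: one row per image pair; `v000_mm` … `v103_mm` is the
  registration vector (view A: 25 grid (I, J) pairs then the PTV pair;
  view B likewise), plus the back-projected PTV position and the
  reference position.
* `tables/cv_{no_dvi,dvi}.csv`: per held-out patient and pooled row;
  min/LQ/median/UQ/max of the 3D error (mm).
* `tables/dose_impact_*.csv`: per structure planned vs expectation
  D95%/D0.5cc (Gy) and differences.
* `tables/dvh_curves.csv`: long format; dose axis (Gy), planned /
  expectation volume fractions and the stochastic min/max band.

## Models (`.json`)

Full 105×3 coefficient matrix (104 components + intercept row), cutoff
ratio R, retained singular-value count, training size.
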
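# Default genotype panel. ku_level is the fraction of wild-type Ku protein;
# cnhej_capacity marks an intact downstream C-NHEJ apparatus; resection_mean
# reflects the hyper-resection seen when Ku is absent.
WT:
  ku_level: 1.0
  cnhej_capacity: true
  resection_mean: 350

Ku70het:
  ku_level: 0.5
  cnhej_capacity: true
  resection_mean: 450

Ku86het:
  ku_level: 0.5
  cnhej_capacity: true
  resection_mean: 450

Ku86null:
  # residual Ku after conditional knockout never reaches exactly zero
  ku_level: 0.05
  cnhej_capacity: true
  resection_mean: 690

DNAPKcsnull:
  ku_level: 1.0
  cnhej_capacity: false
  resection_mean: 350

XLFnull:
  ku_level: 1.0
  cnhej_capacity: false
  resection_mean: 350

LIGIVnull:
  ku_level: 1.0
  cnhej_capacity: false
  resection_mean: 350

LIGIVnull_Ku86het:
  ku_level: 0.5
  cnhej_capacity: false
  resection_mean: 450
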
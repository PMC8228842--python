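# Age-banded reference values used to express raw laboratory results as a
# percentage of the age-specific norm.  Bands are half-open [min, max) in
# months; the last band is open-ended.  Each reference is the midpoint of a
# conventional pediatric interval and is a documented placeholder: the values
# depend on the assay and laboratory, and users should supply their own table
# for real data.  Units: immunoglobulins g/L, B cells percent of lymphocytes.
age_bands_months:
  - [0, 6]
  - [6, 12]
  - [12, 24]
  - [24, 72]
  - [72, null]
references:
  igg: [4.0, 5.5, 6.5, 8.0, 10.0]
  iga: [0.25, 0.45, 0.70, 1.20, 1.80]
  igm: [0.45, 0.65, 0.90, 1.10, 1.20]
  b_cells: [20.0, 20.0, 18.0, 15.0, 12.0]
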
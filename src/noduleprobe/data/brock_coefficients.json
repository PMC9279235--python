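{
  "model": "Brock (PanCan) full model with spiculation",
  "source": "McWilliams A et al. Probability of cancer in pulmonary nodules detected on first screening CT. N Engl J Med 2013;369:910-919, supplementary appendix (model 2b).",
  "notes": "Size enters as -size_coef * ((size_mm/10)^-0.5 - size_center); age is centered at 62 years; nodule count at 4. size_center = (4/10)^-0.5 = sqrt(10)/2.",
  "intercept": -6.7892,
  "age_per_year": 0.0287,
  "age_center_years": 62.0,
  "sex_female": 0.6011,
  "family_history": 0.2961,
  "emphysema": 0.2953,
  "size": -5.3854,
  "size_center": 1.58113883,
  "upper_lobe": 0.6581,
  "part_solid": 0.377,
  "nonsolid": -0.1276,
  "nodule_count_per_nodule": -0.0824,
  "nodule_count_center": 4.0,
  "spiculation": 0.7729
}
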
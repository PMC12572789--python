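# Oxford (Henry 2005) basal-metabolic-rate equations, weight + height form.
# BMR [MJ/day] = a * weight[kg] + b * height[m] + c, per sex and age band;
# converted to kcal/day with 1 MJ = 239.005736 kcal.  Age bands are
# half-open [lo, hi).  The table is editable: any band structure with the
# same fields is accepted.
mj_to_kcal: 239.005736
bands:
  male:
    - {age_lo: 18, age_hi: 30, a: 0.0600, b: 1.31, c: 0.473}
    - {age_lo: 30, age_hi: 60, a: 0.0476, b: 2.26, c: -0.574}
    - {age_lo: 60, age_hi: 200, a: 0.0478, b: 2.26, c: -1.070}
  female:
    - {age_lo: 18, age_hi: 30, a: 0.0433, b: 2.57, c: -1.180}
    - {age_lo: 30, age_hi: 60, a: 0.0342, b: 2.10, c: -0.0486}
    - {age_lo: 60, age_hi: 200, a: 0.0356, b: 1.76, c: 0.0448}
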
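"""Cumulative incidence of CVD by non-HDL category under competing risk.

The Aalen-Johansen estimator accounts for non-CVD death as a competing event;
the 30-year incidences rise monotonically across the five guideline
categories, and Gray's test rejects equality of the category-specific
incidence curves.
"""

import nonhdlrisk as nr

cfg = nr.default_config(n_subjects=50_000, seed=11)
prepared = nr.prepare_cohort(nr.generate_cohort(cfg))

for sex in ("female", "male"):
    sub = prepared[prepared["sex"] == sex]
    curves = nr.aalen_johansen(sub, group="non_hdl_cat")
    cifs = {g: float(curves[g][1].at(30.0)) for g in sorted(curves)}
    pretty = ", ".join(f"cat{g}: {v:.1%}" for g, v in cifs.items())
    print(f"{sex:6s} 30-year CVD incidence  {pretty}")

gray = nr.grays_test(prepared, "non_hdl_cat")
print(f"Gray's test: chi2 = {gray.statistic:.1f} on {gray.df} df, "
      f"p = {gray.p_value:.2g}")
print("(p < 0.05 means the category incidence curves differ beyond chance)")
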
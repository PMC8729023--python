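"""Prevalence estimates, confidence intervals, chi-square association and
the sample-size formula, on published screening counts.

46 of 749 screened children were anisometropic; 25 of 350 girls and 21 of
399 boys.  The uncorrected Pearson test asks whether gender and
anisometropia are associated.
"""

from anisoprev import chi_square, prevalence, round_half_up, sample_size

overall = prevalence(46, 749)
print(f"overall anisometropia: {overall.numerator}/{overall.denominator} "
      f"= {overall.pct(1)}%  (Wilson 95% CI "
      f"{100 * overall.ci_low:.1f}-{100 * overall.ci_high:.1f}%)")

res = chi_square([[25, 325], [21, 378]])
print(f"gender association: chi2 = {res.statistic:.2f}, df = {res.df}, "
      f"p = {round_half_up(res.p_value, 2)} "
      f"({'significant' if res.significant else 'not significant'} at 0.05)")

ss = sample_size(confidence=0.95, margin=0.05, p=0.5)
print(f"sample size for an unknown proportion at 95% confidence, 5% margin: "
      f"raw {ss.raw:.2f} -> minimum {ss.minimum} "
      f"(conservative {ss.conservative})")
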
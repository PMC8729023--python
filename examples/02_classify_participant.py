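"""Classify one participant from averaged readings: per-eye refractive
states, interocular differences, anisometropia type/severity, and the
person-level category.

The participant below is a 7-year-old with a clearly hyperopic right eye
and an emmetropic left eye: a 2.25 D spherical interocular difference.
"""

from anisoprev import (RefractiveCriteria, classify_aniso, classify_eye,
                       classify_person, compute_aniso, mean_refraction,
                       SpheroCylinder)

criteria = RefractiveCriteria()  # instrument-recommended thresholds

re_readings = [SpheroCylinder(2.75, -0.50, 95),
               SpheroCylinder(2.50, -0.50, 92),
               SpheroCylinder(2.75, -0.25, 99)]
le_readings = [SpheroCylinder(0.50, -0.25, 88),
               SpheroCylinder(0.25, -0.25, 85),
               SpheroCylinder(0.50, 0.00, 0)]

re_pv = mean_refraction(re_readings)
le_pv = mean_refraction(le_readings)
age = 7
re_state = classify_eye(re_pv, re_pv.cylinder, age, criteria)
le_state = classify_eye(le_pv, le_pv.cylinder, age, criteria)
print(f"RE mean SE {re_pv.se:+.2f} D -> {re_state.se_state}"
      f"{' + astigmatism' if re_state.astigmatic else ''}")
print(f"LE mean SE {le_pv.se:+.2f} D -> {le_state.se_state}")

metrics = compute_aniso(re_pv, le_pv)
profile = classify_aniso(metrics, re_state, le_state, criteria)
person = classify_person(re_state, le_state, profile, criteria)
print(f"SA = {metrics.sa:.2f} D, MA = {metrics.ma:.2f} D "
      f"(cutoff {criteria.aniso_cutoff} D)")
print(f"anisometropia: type={profile.aniso_type}, severity={profile.severity}")
print(f"person-level category: {person.category}")
print("  the interocular difference outranks the hyperopia label: this "
      "child counts as an anisometrope, not a hyperope")
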
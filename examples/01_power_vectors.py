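"""Convert sphero-cylindrical readings to power vectors and average
replicates without axis artifacts.

Averaging raw axes is wrong near the 0/180 wrap: two cylinders at 10 and
170 degrees nearly cancel in their oblique component, they do not point
at 90 degrees.  The (SE, J0, J45) representation makes this an ordinary
component-wise mean.
"""

from anisoprev import SpheroCylinder, from_power_vector, mean_refraction, \
    to_power_vector

reading = SpheroCylinder(sphere=0.0, cylinder=-2.0, axis=45.0)
pv = to_power_vector(reading)
print(f"(S=0, C=-2.00, axis=45)  ->  SE={pv.se:+.2f}  J0={pv.j0:+.2f}  "
      f"J45={pv.j45:+.2f}")
print("  all the astigmatism is oblique (J45), none with/against the rule")

back = from_power_vector(pv)
print(f"inverse: S={back.sphere:+.2f} C={back.cylinder:+.2f} "
      f"axis={back.axis:.0f}  (round trip)")

replicates = [SpheroCylinder(0.0, -1.0, 10.0), SpheroCylinder(0.0, -1.0, 170.0)]
mean = mean_refraction(replicates, min_count=2)
print(f"mean of C=-1.00 at 10 and 170 deg: J0={mean.j0:+.3f} "
      f"J45={mean.j45:+.3f}")
print("  J45 cancels; a naive axis average to 90 deg would flip J0's sign")
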
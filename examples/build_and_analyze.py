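"""Build the drug-DNA complex at its refined geometry and measure it back.

Constructs the 15-mer estrogen-response-element duplex with the four
intercalation gaps opened (two per drug copy), then reports per-step rise
and twist from the frame analyzer.  The printed rises at steps 5, 7, 9
and 11 (1-based) are the enlarged intercalation gaps; unwinding sums over
each drug's 3-step footprint.
"""

from noefold import (compute_frames, make_ground_truth,
                     tff1_complex_spec, site_unwinding, step_parameters)

spec = tff1_complex_spec()
complex_ = make_ground_truth(spec)
print(f"complex: {complex_.n_atoms} atoms "
      f"({len(set(complex_.mols))} molecules)")

steps = step_parameters(compute_frames(complex_, spec.topology))
print("\nstep  rise(A)  twist(deg)  unwinding(deg)")
for p in steps:
    mark = " <- gap" if p.rise > 5 else ""
    print(f"{p.step + 1:4d}  {p.rise:7.2f}  {p.twist:10.2f}  "
          f"{p.unwinding:13.2f}{mark}")

print(f"\nunwinding over the first drug site (steps 5-7):  "
      f"{site_unwinding(steps, 4, 6):.1f} deg")
print(f"unwinding over the second drug site (steps 9-11): "
      f"{site_unwinding(steps, 8, 10):.1f} deg")
# the gaps carry ~6 A rises vs 3.4 A elsewhere; the two sites unwind the
# helix by ~32 and ~28 degrees against the 36 deg/step reference
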
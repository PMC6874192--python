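"""Pelvis-like phantoms: dense bone crossing the beam path drives the
patient scatter factor above unity, roughly linearly in the dense-bone
percentage of the field.

Run:  python examples/03_pelvis_bone_sweep.py
"""

import protoscatter as ps
from protoscatter.models import fit_line

rows = []
for frac in (0.0, 0.02, 0.04, 0.06, 0.08):
    cfg = ps.RunConfig(phantom_kind="pelvis", heterogeneity_fraction=frac, seed=3,
                       shape=(72, 72, 72), spacing_mm=4.0, bev_radius_mm=40.0,
                       field_radius_cm=3.5, beamlet_spacing_cm=0.4)
    row = ps.run_scenario(cfg)
    rows.append(row)
    print(f"dense bone {row['dense_bone_pct']:5.2f}%  ->  PSF {row['psf']:.4f}")

fit = fit_line([r["dense_bone_pct"] for r in rows], [r["psf"] for r in rows],
               predictor_name="dense_bone_pct")
print(f"\nlinear fit: PSF = {fit.intercept:.4f} {fit.slope:+.5f} * dense-bone%  "
      f"(r^2 = {fit.r2:.3f})")
print("Bone is denser than water, so the matched water-equivalent depth "
      "sits geometrically deeper in water than in the patient; the shorter "
      "source distance and tighter beam in the patient raise the dose there.")
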
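"""Measure the five root phenotype traits and compare with ground truth.

RTN (root count), RTL (total length, mm), RTW (mean width, mm), REL
(horizontal extension, mm) and REA (angle between the two longest roots,
degrees) are extracted from a clean synthetic image at 0.1 mm/px.
"""

from rootpcj import generate_root_system, measure, relative_error, repair

mask, truth = generate_root_system(n_roots=5, rng_seed=1)
record = measure(repair(mask))

rtl_truth = truth.total_arc_px * truth.mm_per_px
print(f"RTN = {record.rtn} roots   (truth: {truth.n_roots})")
print(f"RTL = {record.rtl_mm:.1f} mm  (truth: {rtl_truth:.1f} mm, "
      f"error {relative_error(rtl_truth, record.rtl_mm)}%)")
print(f"RTW = {record.rtw_mm:.2f} mm  (mean generated width: "
      f"{truth.mean_width_px * truth.mm_per_px:.2f} mm)")
print(f"REL = {record.rel_mm:.1f} mm  (truth: "
      f"{truth.rel_px * truth.mm_per_px:.1f} mm)")
print(f"REA = {record.rea_deg:.1f} deg between the two longest roots")
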
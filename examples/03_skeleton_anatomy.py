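"""Dissect the skeleton stages: thinning, feature points, arc labeling.

Shows the intermediate objects the repair is built from: the unit-width
skeleton, its endpoints and bifurcations, and the serial-numbered arcs
produced by progressive corrosion.
"""

from rootpcj import (corrode, extract_feature_points, generate_root_system,
                     init_state, segments_from_labels, thin)

mask, truth = generate_root_system(n_roots=4, rng_seed=7)
skeleton = thin(mask)
fps = extract_feature_points(skeleton)
labels = corrode(skeleton, init_state(skeleton, fps))
segments = segments_from_labels(labels)

print(f"mask foreground: {int(mask.sum())} px "
      f"-> skeleton: {int(skeleton.sum())} px")
print(f"endpoints: {len(fps.endpoints)} (root tips + collar area), "
      f"bifurcations: {len(fps.bifurcations)}")
print(f"arcs labeled: {labels.max()} "
      f"(junction pixels: {int((labels == -1).sum())})")
longest = max(segments, key=lambda s: s.length_px)
print(f"longest arc: id {longest.id}, {longest.length_px} px, "
      f"from {longest.ends[0]} to {longest.ends[1]}")
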
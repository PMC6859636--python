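"""Simulate an occluded root image, repair it, and score the repair.

Generates a 5-root synthetic system, punches three soil gaps through it,
runs the full repair pipeline, and compares the bridges against the known
gap registry.
"""

from rootpcj import (PipelineConfig, generate_root_system, occlude, repair,
                     score_recovery)

clean, truth = generate_root_system(n_roots=5, rng_seed=1)
gapped, truth = occlude(clean, truth, n_gaps=3, rng_seed=2)

result = repair(gapped, PipelineConfig())
metrics = score_recovery(result.repaired_mask, result.joins, truth)

print("stage counts:", result.stats)
print(f"gaps punched: {metrics.n_gaps}, bridges drawn: {metrics.n_joins}")
print(f"rejoin rate:  {metrics.rejoin_rate:.2f} "
      f"(fraction of gaps whose true flanks were reconnected)")
print(f"wrong joins:  {metrics.wrong_joins} "
      f"(bridges connecting pixels of two different roots)")
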
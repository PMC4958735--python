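"""Score a synthetic core with the universal classifier.

Generates a core whose true Ki67 fraction is known, runs the full
colour-deconvolution + HSI gating + watershed + shape-filter pipeline,
and compares the automated score with the truth.  The difference is the
pipeline's per-core scoring error.
"""

from ki67tma import CoreSpec, generate_core, score_core, universal_config

spec = CoreSpec(core_id="demo", n_nuclei=1000, positive_fraction=0.2, seed=7)
image, truth = generate_core(spec)
result = score_core(image, universal_config())

print(f"ground truth : {truth.n_positive} positive / {truth.n_negative} negative "
      f"-> {truth.true_ki67:.1f} %")
print(f"automated    : {result.n_positive} positive / {result.n_negative} negative "
      f"-> {result.ki67_percent:.1f} %")
print(f"score error  : {abs(result.ki67_percent - truth.true_ki67):.2f} percentage points")
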
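"""Empirical-null thresholding, the filtering cascade, and region calling.

Injects a run of three physically adjacent mare-distorted SNPs, builds the
gene-drop null distribution of the |TRD| estimator, applies the four-gate
candidate cascade (decisive Bayes factor, null threshold, >20 informative
offspring, |TRD| > 0.2), and chains the survivors into regions.
"""

from trioscan import ParentSpecificParams, ScanConfig
from trioscan.scan import (
    apply_results_cascade,
    build_empirical_null,
    call_regions,
    regions_table,
    scan,
)
from trioscan.simulate import SimConfig, TrdLocus, simulate_panel

# three linked SNPs on one chromosome with the same mare-side distortion
loci = [TrdLocus(i, "allelic_parent_specific", ParentSpecificParams(0.0, 0.35)) for i in (40, 41, 42)]
panel = simulate_panel(SimConfig(n_snps=120, maf=0.35, seed=4, trd_loci=loci))

cfg = ScanConfig(seed=4)
results = scan(panel.trios, cfg)
null = build_empirical_null(panel.trios, margin=0.001, n_reps=10_000, seed=4, cfg=cfg)
print(f"gene-drop null threshold (99.9% of |TRD| under Mendelian transmission): {null.threshold_at_margin:.3f}")

report = apply_results_cascade(results, null)
print("\ncascade gate counts:")
print(report.to_frame().to_string(index=False))

regions = call_regions(results, max_gap_bp=1_000_000, min_snps=2)
print("\nregions of physically linked, same-pattern SNPs:")
print(regions_table(regions).to_string(index=False))
print(
    "\nThe three injected SNPs sit 100 kb apart on one chromosome and share the\n"
    "mare pattern, so they chain into a single region when they survive the\n"
    "cascade; the null threshold (~0.14 at these informative counts) separates\n"
    "chance magnitudes from the injected 0.35 distortion."
)
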
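"""Coverage and source diversity on hand-built weight vectors.

Edge weights are supply/requirement ratios per source; coverage is their
sum and source diversity the exponentiated Shannon entropy of the shares —
the effective number of equally important sources.
"""

from nutrinet import classify_coverage, coverage, source_diversity

for label, weights in [
    ("single source", [0.9]),
    ("two equal sources", [0.45, 0.45]),
    ("three sources, 50/25/25%", [0.50, 0.25, 0.25]),
    ("four sources, 50/25/24/1%", [0.50, 0.25, 0.24, 0.01]),
]:
    nc = coverage(weights)
    sd = source_diversity(weights)
    print(f"{label:28s}  coverage={nc:5.2f}  diversity={sd:5.2f}")

print()
print("A diversity of 2.8 means the nutrient is effectively supplied by")
print("about three, not quite equally important, sources.")
print()
band = classify_coverage(nc_ear=1.2, nc_rni=0.9)
print(f"coverage 1.2 x EAR but 0.9 x RNI -> band: {band}")
print("(supply meets the average requirement but not the recommended intake)")
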
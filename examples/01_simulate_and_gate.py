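"""Generate a synthetic MxIF slide and recover its phenotypes by marker gating.

The generator paints elliptical nuclei (plus Muc2-high goblet blobs) into 17
named stain channels at 0.32 um/px; the gating stage computes per-instance
mean intensities, thresholds them, and walks the ordered 14-class rule table.
With the default noise level the rules recover the generative truth almost
perfectly; at zero noise, exactly.
"""

from phenogate import (
    ThresholdSet,
    default_config,
    default_rule_table,
    default_thresholds,
    gate,
    generate_tissue,
)

config = default_config(n_cells=400, noise_sd=0.08, seed=7)
tissue = generate_tissue(config)
print(f"generated {tissue.instances.n_instances} instances "
      f"on a {tissue.image.shape} slide with {len(tissue.image.channels)} channels")

cells = gate(
    tissue.image,
    tissue.instances,
    default_rule_table(),
    ThresholdSet(default_thresholds(), config.slide_id),
)

merged = cells.merge(
    tissue.truth[["instance_id", "class"]].rename(columns={"class": "true_class"}),
    on="instance_id",
)
accuracy = (merged["class"] == merged["true_class"]).mean()

print("\ngated class counts (one label per instance):")
print(cells["class"].value_counts().to_string())
print(f"\ngating accuracy vs generative truth: {accuracy:.4f}")
print("(each instance's mean stain intensities, thresholded per channel, feed the"
      " ordered rule cascade; specific markers fire before lineage-generic ones)")
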
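"""Extract cytosine-centered windows from a sequence and encode them.

Every cytosine in a query yields a 41-nt window (flank 20, N-padded at the
ends).  Each window is turned into a numeric vector by six feature
families; position-specific families (PSNP/KSPSDP) need propensity
matrices fitted on labeled data first.
"""

import numpy as np

from m5cpred import (
    FeatureSpec,
    SyntheticSpec,
    build_feature_matrix,
    encode_cpd,
    encode_knf,
    extract_fragments,
    fit_propensities,
    generate_dataset,
    normalize_sequence,
)

seq = normalize_sequence("augGCCAUCGGAUACGCUUAGCCAUGGAACCUAGCUAAUCGGAUU", "demo")
fragments = extract_fragments(seq, lambda_flank=20)
print(f"{seq.id}: {len(seq)} nt, {len(fragments)} cytosine-centered windows")
for frag in fragments[:3]:
    print(f"  C at position {frag.center_pos_1based}: {frag.window}")

frag = fragments[0]
print(f"\n4NF vector: {encode_knf(frag, 4).shape[0]} k-mer frequencies, "
      f"sum = {encode_knf(frag, 4).sum():.3f} (N-padding excluded from counts)")
print(f"CPD vector: {encode_cpd(frag).shape[0]} values "
      "(chemical triple + prefix density per position)")

# Propensity features require a labeled training set
train = generate_dataset(SyntheticSpec(
    n_pos=100, n_neg=100, seed=1,
    pwm_effect={19: {"G": 6.5}, 23: {"G": 6.5}},
))
model = fit_propensities(train, gaps=(1,))
print(f"\nPSNP matrix: {model.psnp.shape}, center column all-zero: "
      f"{not model.psnp[:, 20].any()}")
print("largest |propensity| at positions:",
      np.argsort(np.abs(model.psnp).max(axis=0))[-2:] + 1,
      "(the planted motif positions)")

spec = FeatureSpec.parse(["PSNP", "4NF", "1SPSDP", "PseDNC"])
fm = build_feature_matrix(train, spec, model)
print(f"\nfeature matrix for '{spec.name}': {fm.data.shape} "
      "(41 + 256 + 39 + 18 columns)")
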
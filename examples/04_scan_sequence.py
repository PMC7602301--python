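"""Scan a query RNA for candidate m5C sites with a trained model.

Every cytosine gets a 41-nt window (ends N-padded, as a site-scanning
server does) and an SVM decision value; score >= 0 calls the site.
"""

from m5cpred import (
    FeatureSpec,
    SVMGrid,
    SyntheticSpec,
    extract_fragments,
    generate_dataset,
    normalize_sequence,
    predict_scores,
    train_on_dataset,
)

train = generate_dataset(SyntheticSpec(
    n_pos=200, n_neg=200, seed=5,
    pwm_effect={18: {"G": 6.5}, 19: {"G": 6.5}, 23: {"A": 6.5}, 24: {"G": 6.5}},
))
model = train_on_dataset(
    train, FeatureSpec.parse(["PSNP"]), SVMGrid.coarse(4), seed=5
)

# query with one motif-flanked cytosine: GG at center-3/-2, A/G at center+2/+3
query = normalize_sequence(
    "AUAUAUAUAUAUAUAUAGGUCUAGUAUAUAUAUAUAUAUAUACAUAUUUACGUAU", "query1"
)
fragments = extract_fragments(query, model.lambda_flank)
print(f"{query.id}: {len(query)} nt, {len(fragments)} cytosines scanned\n")
print("position  score    call")
for frag, (score, label) in zip(fragments, predict_scores(model, fragments)):
    call = "m5C" if label else "-"
    print(f"{frag.center_pos_1based:8d}  {score:+.3f}  {call}")
print("\n(the cytosine in the planted GG..C..AG context scores highest)")
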
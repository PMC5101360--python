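"""Train a ternary-complete ECOC ensemble and watch one decoding happen.

The codeword is the vector of hard outputs of the six binary learners;
loss-weighted decoding picks the class row minimising the aggregated
Hamming loss.
"""

from colonyqc import (
    KNNSpec,
    SyntheticFeatureConfig,
    build_coding_matrix,
    decode,
    generate_feature_table,
    predict_codeword,
    train_ecoc,
)

table = generate_feature_table(SyntheticFeatureConfig(
    class_counts={"bad": 15, "good": 15, "semigood": 15},
    separation=5.0, seed=4,
))
cm = build_coding_matrix("ternary_complete", 3, table.class_order())
model = train_ecoc(table, cm, KNNSpec(k=3, distance="cityblock"))

print("per-column training subset sizes:", model.column_subset_sizes)
x = table.features[0]   # a row whose true grade is 'bad'
s = predict_codeword(model, x)
row = decode(cm, s)
print("codeword for one bad-colony vector:", s.tolist())
print("decoded class:", model.class_labels[row], "(truth: bad)")
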
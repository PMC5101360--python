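"""Leave-one-out and nested leave-one-out on synthetic colony features.

LOO evaluates parameter-free learners; for k-NN the nested variant also
selects k per outer fold by an inner LOO, so the reported accuracy never
uses a k tuned on the held-out example.
"""

from colonyqc import (
    DiscriminantSpec,
    KNNSpec,
    SyntheticFeatureConfig,
    generate_feature_table,
    loo_evaluate,
    nloo_evaluate,
)

table = generate_feature_table(SyntheticFeatureConfig(
    class_counts={"bad": 8, "good": 14, "semigood": 11},
    separation=3.0, seed=7,
))

m = loo_evaluate(table, "ova", DiscriminantSpec(variant="diag_linear"))
print("LOO, one-vs-all diagonal LDA:", m.render_row())

res = nloo_evaluate(table, "ovo", KNNSpec(k=1, distance="euclidean"),
                    k_grid=(1, 3, 5))
print("NLOO, one-vs-one Euclidean k-NN:", res.metrics.render_row())
print("k selected per outer fold:", res.selected_k)
print("(each cell: true positives and per-class sensitivity; "
      "ACC = overall proportion correct)")
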
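"""Build the four ECOC coding designs for the three colony quality grades.

Rows are class codewords (bad, good, semigood), columns are the binary
dichotomies each base learner is trained on; 0 excludes a class.
"""

from colonyqc import build_coding_matrix, expected_column_count, validate_coding_matrix

CLASSES = ["bad", "good", "semigood"]

for design in ("ova", "ovo", "ordinal", "ternary_complete"):
    cm = build_coding_matrix(design, 3, CLASSES)
    print(f"\n{design} ({cm.n_columns} binary learners):")
    for label, row in zip(cm.class_labels, cm.entries):
        print(f"  {label:>9}: {row.tolist()}")
    assert validate_coding_matrix(cm) == []

print("\ncolumn counts by class count M (ternary complete grows as 3^M):")
for M in range(2, 7):
    counts = {d: expected_column_count(d, M)
              for d in ("ova", "ovo", "ordinal", "ternary_complete")}
    print(f"  M={M}: {counts}")
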
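"""Score the packaged 22-mutation literature validation table.

Ground truth derives from the phenotype column: hypercalcemia implies a
loss-of-function mutation, hypocalcemia a gain-of-function one.  The printed
predictions are compared against that truth; F1 takes loss-of-function (the
majority clinical class) as positive.
"""

from subspec.classifier import score_table2_fixture
from subspec.synthetic import table2_fixture

df = table2_fixture()
print(df.to_string(index=False))

r = score_table2_fixture()
print(f"\naccuracy: {r['accuracy']:.2f} ({r['n_correct']}/{r['n']} predictions "
      "match the phenotype-derived truth)")
print(f"F1 (loss-of-function positive): {r['f1']:.2f}")
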
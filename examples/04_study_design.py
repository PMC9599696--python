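"""Sample-size planning for a correlation-based validation study.

How many subjects are needed so that the Fisher confidence interval of
a Pearson correlation has a prescribed width?  The two-stage
approximation first sizes the study from the large-sample width
formula, then corrects with the width actually achieved at that size.
"""

from fmascore import sample_size_pearson_two_stage

for r, width, alpha in [(0.9, 0.3, 0.01), (0.9, 0.2, 0.01),
                        (0.8, 0.3, 0.05), (0.5, 0.3, 0.05)]:
    n = sample_size_pearson_two_stage(r, width, alpha)
    print(f"planning r={r:.1f}  width={width:.1f}  alpha={alpha:.2f}"
          f"  ->  n = {n:3d} subjects")
# At planning correlation 0.9, interval width 0.3 and alpha 0.01 the
# method calls for 20 subjects; tighter intervals or weaker expected
# correlations require more.
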
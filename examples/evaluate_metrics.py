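"""Precision / recall / F-measure on a small worked confusion.

Identification metrics come from span matching; polarity metrics are
one-vs-rest per class, then macro- (equal class weight) and micro-
(pooled counts) averaged.
"""

from aspectsent import f_measure, prf_from_counts
from aspectsent.evaluate import polarity_report_from_pairs

prf = prf_from_counts(tp=3, fp=1, fn=2)
print(f"identification: P={prf.precision:.2f} R={prf.recall:.2f} "
      f"F={prf.f_measure:.2f}")
print(f"harmonic mean of P=85.71, R=80.00: F={f_measure(85.71, 80.00):.2f}")

# gold (pos, pos, neg, neu) vs predicted (pos, neg, neg, neu)
labelled = [("positive", "positive"), ("negative", "positive"),
            ("negative", "negative"), ("neutral", "neutral")]
report = polarity_report_from_pairs(labelled)
for cls, p in report.per_class.items():
    print(f"{cls:9s} P={p.precision:6.2f} R={p.recall:6.2f} F={p.f_measure:6.2f}")
print(f"macro     P={report.macro.precision:6.2f} R={report.macro.recall:6.2f} "
      f"F={report.macro.f_measure:6.2f}")
print(f"micro     P={report.micro.precision:6.2f} R={report.micro.recall:6.2f} "
      f"F={report.micro.f_measure:6.2f}")
# Note the macro F is the mean of per-class F values, which is generally
# not the harmonic mean of macro P and macro R.
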
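"""Positivity percentage: the statistic everything else estimates.

Builds a tiny judgment by hand and computes its positivity — the share
of clicked nuclei labelled positive, the clinical labelling index for
proliferation markers such as Ki-67/MIB1.
"""

from crowdihc import Click, Judgment, NucleusClass, Point, judgment_positivity, positivity

print("positivity(79 positive, 41 negative) =", round(positivity(79, 41), 2), "%")

clicks = [Click(Point(10 * i, 50), NucleusClass.POSITIVE) for i in range(3)]
clicks += [Click(Point(10 * i, 150), NucleusClass.NEGATIVE) for i in range(9)]
judgment = Judgment(image_id="demo", worker_id="w0", clicks=clicks)
print("judgment with 3 P / 9 N clicks  =", round(judgment_positivity(judgment), 2), "%")

# Meaning: 65.83% of the 120 counted nuclei are stained; the worker's
# 12-click judgment estimates a 25% labelling index for its image.
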
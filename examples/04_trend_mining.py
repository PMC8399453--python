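"""Dosage-form trend mining on a small hand-built corpus.

Patents are matched against a form lexicon over their cleaned lemma
streams (so tablet/tablets/Tablet are the same), and counted once per
form per patent, by publication year.
"""

from patentscape import PatentRecord, default_lexicon, trend_series

corpus = [
    PatentRecord("P1", 2001, "inclusion complex", "formulated as oral tablets"),
    PatentRecord("P2", 2001, "improved solubility", "chewable tablet composition"),
    PatentRecord("P3", 2003, "thermoreversible system", "topical gel for nails"),
    PatentRecord("P4", 2004, "aqueous solution of drug", "parenteral solution"),
    PatentRecord("P5", None, "stable powder", "dry powder for inhalation"),
]

series = trend_series(corpus, default_lexicon())
print(series.totals_frame()[series.totals_frame()["total"] > 0].to_string(index=False))
print()
print(series.to_frame().to_string(index=False))
# 'total' counts every matching patent; P5 has no usable year, so it
# appears in the totals (and missing_year) but not in the yearly series.
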
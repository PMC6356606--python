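"""Parse a small cohort CSV and print the per-patient composite scores.

Pattern cells may be letters (A/B/C) or digits (0/1/2). Each patient gets
three composites: Overall (sum of all seven ordinal codes), Partial B
(count of Pattern-B subsites) and Partial C (twice the count of Pattern-C
subsites); Overall = Partial B + Partial C by construction.
"""

from plcscore import parse_cohort, score_cohort

csv_text = """\
patient_id,post_vm,post_pgs,inf_pgs,ary,cric_lam,lcam,ctm,histology
alpha,C,B,A,A,A,C,A,1
beta,B,B,A,A,A,A,A,0
gamma,A,A,A,A,A,A,A,0
"""

table = score_cohort(parse_cohort(csv_text))
print("patient  overall  partial_b  partial_c  histology")
for pid, t, h in table.rows:
    print(f"{pid:<8} {t.overall:^8} {t.partial_b:^9} {t.partial_c:^9} {h:^9}")
# alpha has two Pattern-C subsites (partial_c 4) and one B (partial_b 1):
# overall 5. A score of 2+ (any C subsite) is the rule-in signal for
# neoplastic infiltration.
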
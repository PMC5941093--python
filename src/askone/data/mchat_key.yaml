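# Default M-CHAT-R scoring key.
#
# risk_if_yes: for each of the 20 items, whether a "yes" answer indicates
# developmental risk. Under the published scoring convention, "yes" indicates
# risk on items 2, 5 and 12; for all other items "no" indicates risk.
# The engine treats items abstractly (Q1..Q20); display labels come from
# this file and carry no copyrighted item text.
risk_if_yes:
  Q1: false
  Q2: true
  Q3: false
  Q4: false
  Q5: true
  Q6: false
  Q7: false
  Q8: false
  Q9: false
  Q10: false
  Q11: false
  Q12: true
  Q13: false
  Q14: false
  Q15: false
  Q16: false
  Q17: false
  Q18: false
  Q19: false
  Q20: false
labels:
  Q1: "Q1"
  Q2: "Q2"
  Q3: "Q3"
  Q4: "Q4"
  Q5: "Q5"
  Q6: "Q6"
  Q7: "Q7"
  Q8: "Q8"
  Q9: "Q9"
  Q10: "Q10"
  Q11: "Q11"
  Q12: "Q12"
  Q13: "Q13"
  Q14: "Q14"
  Q15: "Q15"
  Q16: "Q16"
  Q17: "Q17"
  Q18: "Q18"
  Q19: "Q19"
  Q20: "Q20"
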
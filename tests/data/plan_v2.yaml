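label: v2
iterations:
- label: v2-01 DOB+SEX+COB+PC1
  selectors:
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(1)
- label: v2-02 DOB+SEX+COB+PC2
  selectors:
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(2)
- label: v2-03 DOB+SEX+COB+PC3
  selectors:
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(3)
- label: v2-04 DOB+SEX+COB+PC4
  selectors:
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(4)
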
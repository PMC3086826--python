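label: v2s
iterations:
- label: v2s-01 SUF+DOB+SEX+COB+PC1
  selectors:
  - SUFFIX_FULL
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(1)
- label: v2s-02 SUF+DOB+SEX+COB+PC2
  selectors:
  - SUFFIX_FULL
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(2)
- label: v2s-03 SUF+DOB+SEX+COB+PC3
  selectors:
  - SUFFIX_FULL
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(3)
- label: v2s-04 SUF+DOB+SEX+COB+PC4
  selectors:
  - SUFFIX_FULL
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(4)
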
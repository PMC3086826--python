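label: v1
iterations:
- label: v1-01 M8+SUF
  selectors:
  - MEDICARE8
  - SUFFIX_FULL
- label: v1-02 M8+SUF(1,2)+SEX
  selectors:
  - MEDICARE8
  - SUFFIX_LETTERS(1,2)
  - SEX
- label: v1-03 M8+SUF(2,3)+SEX
  selectors:
  - MEDICARE8
  - SUFFIX_LETTERS(2,3)
  - SEX
- label: v1-04 M8+SUF(1,3)+SEX
  selectors:
  - MEDICARE8
  - SUFFIX_LETTERS(1,3)
  - SEX
- label: v1-05 M8+YEAR+SEX
  selectors:
  - MEDICARE8
  - YEAR
  - SEX
- label: v1-06 SUF+DOB+SEX+COB+PC1
  selectors:
  - SUFFIX_FULL
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(1)
- label: v1-07 SUF+DOB+SEX+COB+PC2
  selectors:
  - SUFFIX_FULL
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(2)
- label: v1-08 SUF+DOB+SEX+COB+PC3
  selectors:
  - SUFFIX_FULL
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(3)
- label: v1-09 SUF+DOB+SEX+COB+PC4
  selectors:
  - SUFFIX_FULL
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(4)
- label: v1-10 DOB+SEX+COB+PC1
  selectors:
  - YEAR
  - MONTH
  - DAY
  - SEX
  - COB
  - POSTCODE_SLOT(1)
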
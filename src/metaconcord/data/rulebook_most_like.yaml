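# Five-drug panel modeled on a basket-trial design (mTOR, ABL, multi-kinase,
# VEGFR and ERBB2 arms). Placeholder drugs carry empty triggers.
trial: most_like
drugs:
  - name: everolimus
    pathway: PI3K/AKT/mTOR
    triggers:
      - {gene: PIK3CA, alteration: activating_mutation}
      - {gene: AKT1, alteration: activating_mutation}
      - {gene: PTEN, alteration: biallelic_inactivation}
  - name: nilotinib
    pathway: ABL/KIT
    triggers: []
  - name: sorafenib
    pathway: multi-kinase
    triggers: []
  - name: pazopanib
    pathway: VEGFR
    triggers: []
  - name: lapatinib
    pathway: ERBB2
    triggers:
      - {gene: ERBB2, alteration: amplification}
      - {gene: ERBB2, alteration: activating_mutation}
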
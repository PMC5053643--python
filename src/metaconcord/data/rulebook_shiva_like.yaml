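# Seven-drug panel modeled on a molecularly-guided trial design.
# Only the drugs whose trigger logic the study's results imply ship with
# triggers; the rest are placeholders users must populate from the trial
# protocol before use.
trial: shiva_like
drugs:
  - name: imatinib
    pathway: KIT/ABL/PDGFR
    triggers: []
  - name: everolimus
    pathway: PI3K/AKT/mTOR
    triggers:
      - {gene: PIK3CA, alteration: activating_mutation}
      - {gene: AKT1, alteration: activating_mutation}
      - {gene: PTEN, alteration: biallelic_inactivation}
  - name: vemurafenib
    pathway: RAF/MEK/ERK
    triggers: []
  - name: sorafenib
    pathway: multi-kinase
    triggers: []
  - name: erlotinib
    pathway: EGFR
    triggers: []
  - name: dasatinib
    pathway: SRC/ABL
    triggers: []
  - name: lapatinib+trastuzumab
    pathway: ERBB2
    triggers:
      - {gene: ERBB2, alteration: amplification}
      - {gene: ERBB2, alteration: activating_mutation}
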
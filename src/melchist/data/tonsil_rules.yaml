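# Tonsil gating rules for the 12-marker miniature panel.
# Cell definitions follow the conventional cytometry phenotypes:
#   B (CD45+CD19+), T helper (CD45+CD3+CD4+), cytotoxic T (CD45+CD3+CD8+),
#   plasma (CD138+), myeloid (CD14+ within this panel), endothelial (CD31+),
#   ILC (Lin- CD45+ CD127+ with Lin = CD3, CD19, CD14 here).
# Lower priority is evaluated first; the ILC rule runs last (but before the
# "others" fall-through) and relies only on its own inclusion/exclusion
# markers, so multi-positive cells resolve deterministically.
rules:
  - type: B
    priority: 10
    positive: [CD45, CD19]
  - type: T_helper
    priority: 20
    positive: [CD45, CD3, CD4]
  - type: T_cytotoxic
    priority: 30
    positive: [CD45, CD3, CD8]
  - type: plasma
    priority: 40
    positive: [CD138]
  - type: myeloid
    priority: 50
    any_of:
      - [CD14+]
  - type: endothelial
    priority: 60
    positive: [CD31]
  - type: ILC
    priority: 70
    positive: [CD45, CD127]
    negative: [CD3, CD19, CD14]
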
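# Receptor panel schema for the phthalate acute-toxicity reference dataset.
# Endpoints are exposure-duration-qualified EC50/LC50 labels; units are mg/L.
receptors:
  green_algae:
    name: Green algae
    endpoint: 96-EC50
  daphnid:
    name: Daphnid
    endpoint: 48-LC50
  mysid:
    name: Mysid
    endpoint: 96-LC50
  fish:
    name: Fish
    endpoint: 96-LC50
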
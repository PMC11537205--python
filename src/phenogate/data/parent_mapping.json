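{
  "parent_of": {
    "helper T": "lymphocyte",
    "cytotoxic T": "lymphocyte",
    "CD3d+ CD4- CD8- T": "lymphocyte",
    "B": "lymphocyte",
    "enterocyte": "epithelial",
    "progenitor": "epithelial",
    "enteroendocrine": "epithelial",
    "fibroblast": "connective",
    "stromal (undetermined)": "connective",
    "macrophage": "myeloid",
    "monocyte": "myeloid",
    "myeloid (other)": "myeloid",
    "leukocyte (other)": "leukocyte"
  },
  "droppable": [
    "goblet"
  ]
}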
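- class: goblet
  positive:
  - Muc2
  negative: []
- class: enteroendocrine
  positive:
  - CgA
  - DAPI
  negative: []
- class: progenitor
  positive:
  - DAPI
  - Sox9
  negative: []
- class: progenitor
  positive:
  - DAPI
  - OLFM4
  negative: []
- class: enterocyte
  positive:
  - DAPI
  - NaKATPase
  - PanCK
  negative: []
- class: helper T
  positive:
  - CD3d
  - CD4
  - DAPI
  negative: []
- class: cytotoxic T
  positive:
  - CD3d
  - CD8
  - DAPI
  negative: []
- class: CD3d+ CD4- CD8- T
  positive:
  - CD3d
  - DAPI
  negative: []
- class: B
  positive:
  - CD20
  - DAPI
  negative: []
- class: macrophage
  positive:
  - CD68
  - DAPI
  negative: []
- class: monocyte
  positive:
  - CD11b
  - DAPI
  negative: []
- class: myeloid (other)
  positive:
  - DAPI
  - Lysozyme
  negative: []
- class: leukocyte (other)
  positive:
  - CD45
  - DAPI
  negative: []
- class: fibroblast
  positive:
  - DAPI
  - SMA
  negative: []
- class: stromal (undetermined)
  positive:
  - DAPI
  - Vimentin
  negative: []
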
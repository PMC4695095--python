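# Animal-hemisphere cell system of the 32-cell ascidian embryo at the
# mid-to-late 32-cell stage.  Eight units, each standing for one bilateral
# pair of equivalent ectodermal blastomeres; four signaling pathways.
#
# SYNTHETIC RECONSTRUCTION: the strength orderings below are not measured
# contact areas.  They are representative chains chosen to be consistent
# with the known source geometry (Admp and Gdf from the posterior b-line
# vegetal cells, with anterior a-line cells ranked by distance; Fgf from
# the vegetal hemisphere, strongest in the neural lineage; Efna.d from the
# whole animal hemisphere with autocrine reception excluded, so peripheral
# cells receive the least) and with the induction outcomes encoded in the
# companion condition roster.  Users with measured per-cell contact areas
# should regenerate the orderings with `boolsense order`.
output: Otx
cells: [a6.5, a6.6, a6.7, a6.8, b6.5, b6.6, b6.7, b6.8]
signals:
  - name: admp
    ordering:
      - [b6.8]
      - [b6.7]
      - [b6.6]
      - [b6.5]
      - [a6.8]
      - [a6.7]
      - [a6.6]
      - [a6.5]
    reception_mask: all
    tethered: false
  - name: efn
    ordering:
      - [a6.7]
      - [a6.6]
      - [b6.6]
      - [b6.7]
      - [a6.8]
      - [b6.8]
      - [b6.5]
      - [a6.5]
    reception_mask: all
    tethered: true
  - name: fgf
    ordering:
      - [a6.5]
      - [b6.5]
      - [a6.6]
      - [b6.6]
      - [a6.7]
      - [b6.7]
      - [a6.8]
      - [b6.8]
    reception_mask: all
    tethered: false
  - name: gdf
    ordering:
      - [b6.8]
      - [b6.7]
      - [b6.6]
      - [b6.5]
      - [a6.8]
      - [a6.7]
      - [a6.6]
      - [a6.5]
    reception_mask: all
    tethered: false
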
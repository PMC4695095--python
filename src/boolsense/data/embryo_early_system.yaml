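# Early 32-cell-stage variant of the animal-hemisphere system.  Only the
# geometry-derived orderings differ from the mid-to-late configuration: at
# this stage the neural-lineage b6.5 pair has barely more exposure to the
# posterior Gdf source than the most anterior cells, so it drops to the
# second-weakest position of the Gdf chain.
#
# SYNTHETIC RECONSTRUCTION: see embryo_mid_late_system.yaml; the same
# caveats apply.
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
      - [a6.8]
      - [a6.7]
      - [a6.6]
      - [b6.5]
      - [a6.5]
    reception_mask: all
    tethered: false
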
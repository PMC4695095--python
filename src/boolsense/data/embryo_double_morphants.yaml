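# The two discriminating double knockdowns performed to resolve the
# truth-table rows left undetermined by the base roster: Admp+Fgf and
# Fgf+Gdf double morphants both lose Otx expression throughout the animal
# hemisphere.
- name: admp_fgf_kd
  overrides: {admp: force0, fgf: force0}
  observed: {a6.5: 0, a6.6: 0, a6.7: 0, a6.8: 0,
             b6.5: 0, b6.6: 0, b6.7: 0, b6.8: 0}
- name: fgf_gdf_kd
  overrides: {fgf: force0, gdf: force0}
  observed: {a6.5: 0, a6.6: 0, a6.7: 0, a6.8: 0,
             b6.5: 0, b6.6: 0, b6.7: 0, b6.8: 0}
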
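# Otx induction outcomes in the animal hemisphere under whole-embryo
# perturbations of the four signaling pathways.  Knockdowns (morpholino)
# are force0; overexpression and bath-applied recombinant protein (bFGF
# mimicking Fgf, BMP4 mimicking Admp/Gdf activity) are force1 with a full
# reception mask.
#
# SYNTHETIC RECONSTRUCTION: the per-cell outcomes are an encoding of the
# published qualitative phenotypes (wild-type neural-lineage expression;
# expansion throughout the ectoderm upon Efna.d knockdown or Admp+Gdf
# double knockdown; loss upon Fgf knockdown or the triple knockdown;
# neural-lineage-restricted expression in the bath rescues), not a
# transcription of a per-embryo scoring table.  a6.7 is scored "unknown"
# wherever expression is neural-lineage-like, because its occasional Otx
# expression is not tightly regulated.
- name: wild_type
  overrides: {}
  observed: {a6.5: 1, a6.6: 0, a6.7: unknown, a6.8: 0,
             b6.5: 1, b6.6: 0, b6.7: 0, b6.8: 0}
- name: admp_kd
  overrides: {admp: force0}
  observed: {a6.5: 1, a6.6: 0, a6.7: unknown, a6.8: 0,
             b6.5: 1, b6.6: 0, b6.7: 0, b6.8: 0}
- name: efn_kd
  overrides: {efn: force0}
  observed: {a6.5: 1, a6.6: 1, a6.7: 1, a6.8: 1,
             b6.5: 1, b6.6: 1, b6.7: 1, b6.8: 1}
- name: fgf_kd
  overrides: {fgf: force0}
  observed: {a6.5: 0, a6.6: 0, a6.7: 0, a6.8: 0,
             b6.5: 0, b6.6: 0, b6.7: 0, b6.8: 0}
- name: gdf_kd
  overrides: {gdf: force0}
  observed: {a6.5: 1, a6.6: 0, a6.7: unknown, a6.8: 0,
             b6.5: 1, b6.6: 0, b6.7: 0, b6.8: 0}
- name: admp_gdf_kd
  overrides: {admp: force0, gdf: force0}
  observed: {a6.5: 1, a6.6: 1, a6.7: 1, a6.8: 1,
             b6.5: 1, b6.6: 1, b6.7: 1, b6.8: 1}
- name: admp_fgf_gdf_kd
  overrides: {admp: force0, fgf: force0, gdf: force0}
  observed: {a6.5: 0, a6.6: 0, a6.7: 0, a6.8: 0,
             b6.5: 0, b6.6: 0, b6.7: 0, b6.8: 0}
- name: admp_oe
  overrides: {admp: force1}
  observed: {a6.5: 1, a6.6: 0, a6.7: unknown, a6.8: 0,
             b6.5: 1, b6.6: 0, b6.7: 0, b6.8: 0}
- name: efn_oe
  overrides: {efn: force1}
  observed: {a6.5: 0, a6.6: 0, a6.7: 0, a6.8: 0,
             b6.5: 0, b6.6: 0, b6.7: 0, b6.8: 0}
- name: fgf_oe
  overrides: {fgf: force1}
  observed: {a6.5: 1, a6.6: 0, a6.7: unknown, a6.8: 0,
             b6.5: 1, b6.6: 0, b6.7: 0, b6.8: 0}
- name: gdf_oe
  overrides: {gdf: force1}
  observed: {a6.5: 1, a6.6: 0, a6.7: unknown, a6.8: 0,
             b6.5: 1, b6.6: 0, b6.7: 0, b6.8: 0}
# Triple morphant (Fgf/Admp/Gdf) rescued with a bath of bFGF + BMP4: the
# bath restores uniform Fgf and Admp/Gdf activity, so the overrides are
# force1 on those three pathways.
- name: triple_kd_bfgf_bmp4
  overrides: {admp: force1, fgf: force1, gdf: force1}
  observed: {a6.5: 1, a6.6: 0, a6.7: unknown, a6.8: 0,
             b6.5: 1, b6.6: 0, b6.7: 0, b6.8: 0}
# Quadruple morphant (plus Efna.d) with the same bath: no differential
# input remains and Otx comes on throughout the ectoderm.
- name: quad_kd_bfgf_bmp4
  overrides: {admp: force1, efn: force0, fgf: force1, gdf: force1}
  observed: {a6.5: 1, a6.6: 1, a6.7: 1, a6.8: 1,
             b6.5: 1, b6.6: 1, b6.7: 1, b6.8: 1}
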
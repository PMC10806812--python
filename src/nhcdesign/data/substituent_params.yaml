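# Electronic donation (sigma, donors positive) and steric bulk (v)
# increments per substituent and site class.  Hydrogen is 0/0 by
# convention.  These are effective increments in arbitrary model units,
# anchored jointly to the bundled calibration anchors (the sigma scale
# is set by the small distance/donation coefficient, so values are not
# literature Hammett/Charton constants).  Only ortho and backbone v
# enter the steric descriptors; meta/para substituents act
# electronically only.
substituents:
  phenyl:
    n_aryl: {sigma: 0.0, v: 0.0}
  methyl:
    ortho: {sigma: 1.0, v: 0.25}
    meta_para: {sigma: 1.0, v: 0.0}
    backbone: {sigma: 1.0, v: 0.5}
  ethyl:
    backbone: {sigma: 0.041667, v: 0.833333}
  isopropyl:
    ortho: {sigma: 1.041667, v: 0.479167}
    meta_para: {sigma: 1.041667, v: 0.0}
    backbone: {sigma: 0.9375, v: 0.902778}
  tert-butyl:
    ortho: {sigma: 1.25, v: 0.875}
    meta_para: {sigma: 1.25, v: 0.0}
    backbone: {sigma: 1.833333, v: 0.972222}
  acetyl:
    ortho: {sigma: -0.1, v: 0.65625}
  methoxycarbonyl:
    ortho: {sigma: -0.09, v: 0.7}
  dimethylamino:
    meta_para: {sigma: 0.3, v: 0.0}
  nitro:
    meta_para: {sigma: -0.3, v: 0.0}
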
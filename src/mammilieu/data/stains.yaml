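# Unit optical-density vectors (RGB order) for the chromogens used in the
# multiplex brightfield panels.  Vectors are normalized on load.
#   purple  = CD3 chromogen (absorbs green)
#   teal    = CD20 / CD163 chromogen (absorbs red)
#   yellow  = CD68 chromogen (absorbs blue)
#   hematoxylin = nuclear counterstain
stains:
  hematoxylin: [0.650, 0.700, 0.290]
  purple: [0.250, 0.930, 0.260]
  teal: [0.930, 0.260, 0.260]
  yellow: [0.150, 0.250, 0.960]
panels:
  triple:
    markers: [CD3, CD20, CD68]
    chromogens: {CD3: purple, CD20: teal, CD68: yellow}
  double:
    markers: [CD68, CD163]
    chromogens: {CD68: yellow, CD163: teal}
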
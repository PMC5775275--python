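{
  "places": [
    {
      "name": "AMP",
      "initial": 0.0,
      "clamped": false
    },
    {
      "name": "Asn",
      "initial": 0.0,
      "clamped": false
    },
    {
      "name": "ASNe",
      "initial": 0.0,
      "clamped": false
    },
    {
      "name": "ASNe-Gln",
      "initial": 0.0,
      "clamped": false
    },
    {
      "name": "ASNe-NH3",
      "initial": 0.0,
      "clamped": false
    },
    {
      "name": "Asp",
      "initial": 0.0,
      "clamped": false
    },
    {
      "name": "ATP",
      "initial": 0.0,
      "clamped": true
    },
    {
      "name": "bAsp-AMP-ASNe-NH3",
      "initial": 0.0,
      "clamped": false
    },
    {
      "name": "Gln",
      "initial": 0.0,
      "clamped": false
    },
    {
      "name": "Glu",
      "initial": 0.0,
      "clamped": false
    },
    {
      "name": "Mg2+",
      "initial": 0.0,
      "clamped": true
    }
  ],
  "reactions": [
    {
      "name": "r1",
      "substrates": {
        "ASNe": 1,
        "Gln": 1
      },
      "products": {
        "ASNe-Gln": 1
      },
      "rate_constant": "k1"
    },
    {
      "name": "r2",
      "substrates": {
        "ASNe-Gln": 1
      },
      "products": {
        "Glu": 1,
        "ASNe-NH3": 1
      },
      "rate_constant": "k2"
    },
    {
      "name": "r3",
      "substrates": {
        "ASNe-NH3": 1,
        "Asp": 1,
        "ATP": 1,
        "Mg2+": 1
      },
      "products": {
        "bAsp-AMP-ASNe-NH3": 1,
        "Mg2+": 1
      },
      "rate_constant": "k3"
    },
    {
      "name": "r4",
      "substrates": {
        "bAsp-AMP-ASNe-NH3": 1
      },
      "products": {
        "Asn": 1,
        "ASNe": 1,
        "AMP": 1
      },
      "rate_constant": "k4"
    },
    {
      "name": "D",
      "substrates": {
        "ASNe-NH3": 1
      },
      "products": {
        "ASNe": 1
      },
      "rate_constant": "kD"
    }
  ]
}
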
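{
  "RT": 1.0,
  "advections": [
    {
      "K_ref": null,
      "downstream": "C2",
      "flow": "Q1",
      "name": "r",
      "upstream": "C1"
    }
  ],
  "flows": [
    {
      "kind": "step",
      "name": "Q1",
      "params": {
        "Q0": 2.0,
        "Q1": 10.0,
        "t_step": 10.0
      }
    }
  ],
  "name": "orifice-lambda0",
  "pipes": [],
  "reactions": [
    {
      "kappa": 1.0,
      "name": "r1",
      "products": [
        [
          "C1",
          1.0
        ]
      ],
      "substrates": [
        [
          "A",
          1.0
        ]
      ]
    },
    {
      "kappa": 1.0,
      "name": "r2",
      "products": [
        [
          "B",
          1.0
        ]
      ],
      "substrates": [
        [
          "C2",
          1.0
        ]
      ]
    }
  ],
  "schema_version": 1,
  "species": [
    {
      "K": 1.0,
      "V": 1.0,
      "chemostat": true,
      "name": "A",
      "profile": null,
      "x0": 2.0
    },
    {
      "K": 1.0,
      "V": 1.0,
      "chemostat": false,
      "name": "C1",
      "profile": null,
      "x0": 1.0
    },
    {
      "K": 1.0,
      "V": 1.0,
      "chemostat": false,
      "name": "C2",
      "profile": null,
      "x0": 1.0
    },
    {
      "K": 1.0,
      "V": 1.0,
      "chemostat": true,
      "name": "B",
      "profile": null,
      "x0": 1.0
    }
  ]
}
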
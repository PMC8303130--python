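{
  "format_version": 1,
  "variables": [
    {
      "name": "Flood",
      "states": [
        "present",
        "absent"
      ]
    },
    {
      "name": "LOSI",
      "states": [
        "present",
        "absent"
      ]
    },
    {
      "name": "PPD",
      "states": [
        "present",
        "absent"
      ]
    },
    {
      "name": "Lsever",
      "states": [
        "present",
        "absent"
      ]
    },
    {
      "name": "Msever",
      "states": [
        "present",
        "absent"
      ]
    }
  ],
  "arcs": [
    [
      "Flood",
      "LOSI"
    ],
    [
      "LOSI",
      "PPD"
    ],
    [
      "PPD",
      "Lsever"
    ],
    [
      "PPD",
      "Msever"
    ]
  ],
  "cpts": [
    {
      "child": "Flood",
      "parents": [],
      "rows": [
        {
          "given": [],
          "p": [
            0.201,
            0.7989999999999999
          ]
        }
      ]
    },
    {
      "child": "LOSI",
      "parents": [
        "Flood"
      ],
      "rows": [
        {
          "given": [
            "present"
          ],
          "p": [
            1.0,
            0.0
          ]
        },
        {
          "given": [
            "absent"
          ],
          "p": [
            0.5244055068836045,
            0.47559449311639546
          ]
        }
      ]
    },
    {
      "child": "PPD",
      "parents": [
        "LOSI"
      ],
      "rows": [
        {
          "given": [
            "present"
          ],
          "p": [
            0.22962962962962966,
            0.7703703703703704
          ]
        },
        {
          "given": [
            "absent"
          ],
          "p": [
            0.11481481481481483,
            0.8851851851851852
          ]
        }
      ]
    },
    {
      "child": "Lsever",
      "parents": [
        "PPD"
      ],
      "rows": [
        {
          "given": [
            "present"
          ],
          "p": [
            0.8145025295109612,
            0.18549747048903875
          ]
        },
        {
          "given": [
            "absent"
          ],
          "p": [
            0.4072512647554806,
            0.5927487352445193
          ]
        }
      ]
    },
    {
      "child": "Msever",
      "parents": [
        "PPD"
      ],
      "rows": [
        {
          "given": [
            "present"
          ],
          "p": [
            0.3558178752107926,
            0.6441821247892074
          ]
        },
        {
          "given": [
            "absent"
          ],
          "p": [
            0.1779089376053963,
            0.8220910623946037
          ]
        }
      ]
    }
  ]
}
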
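{
  "groups": [
    {
      "name": "Croceus",
      "required": [11],
      "forbidden": [6],
      "any_of": [],
      "members": [
        "Cortinarius hadrocroceus",
        "Cortinarius holoxanthus",
        "Cortinarius huronensis",
        "Cortinarius salignus"
      ],
      "note": "Yellow lamellae; colouration dominated by a high content of FDM (11)."
    },
    {
      "name": "Malicorius",
      "required": [6, 11],
      "forbidden": [],
      "any_of": [[12, 15]],
      "members": [
        "Cortinarius cinnamomeus",
        "Cortinarius fervidus",
        "Cortinarius malicorius",
        "Cortinarius pellstonianus",
        "Cortinarius rubrophyllus"
      ],
      "note": "Orange to fire-coloured velum and orange to reddish lamellae; emodin-1-glycoside (6), dermolutein, FDM (11), emodin and 7,7'-biphyscion (15) shared."
    },
    {
      "name": "Ominosus",
      "required": [6, 7, 8],
      "forbidden": [11, 14, 15],
      "any_of": [],
      "members": [
        "Cortinarius ominosus",
        "Cortinarius sphagnogenus"
      ],
      "note": "Red lamellae with brownish pileus and stipe; no FDM (11) or its oxidation products; many pigments at low levels."
    },
    {
      "name": "Sanguineus",
      "required": [7, 13],
      "forbidden": [11],
      "any_of": [],
      "members": [
        "Cortinarius cistoadelphus",
        "Cortinarius purpureus",
        "Cortinarius sanguineus",
        "Cortinarius vitiosus"
      ],
      "note": "Red fruit bodies coloured mainly by dermocybin (13), with dermocybin-1-glycoside (7) characteristic."
    }
  ]
}
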
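{
  "features": [
    {
      "kind": "Hyd",
      "radius": 1.0
    },
    {
      "kind": "Hyd",
      "radius": 1.0
    },
    {
      "kind": "HydA",
      "radius": 0.7
    },
    {
      "kind": "Acc2",
      "radius": 1.0
    }
  ],
  "distances": [
    [
      0.0,
      6.7960516375235525,
      3.0779289594726955,
      5.12582909380342
    ],
    [
      6.7960516375235525,
      0.0,
      3.793600730859207,
      2.4312085969692143
    ],
    [
      3.0779289594726955,
      3.793600730859207,
      0.0,
      2.731423837730555
    ],
    [
      5.12582909380342,
      2.4312085969692143,
      2.731423837730555,
      0.0
    ]
  ],
  "tolerance_scale": 0.5,
  "provenance": "calibrated by elucidation on the T1 orthosteric/allosteric sets with Hyd1-Hyd2 clamped to 7.2 A; tolerance scale 0.5; screen-flag agreement 29/33"
}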
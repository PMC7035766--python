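{
  "note": "Recorded elicitation session. Convention: consequence A is the hypothetical intermediate level on the higher-ranked criterion (worst elsewhere); consequence B is the best level on the lower-ranked criterion (worst elsewhere). The on-screen hypothetical levels of the original session are not recorded; replays choose them by ratio-interval bisection.",
  "alternatives": {
    "ATS": "Australasian Triage Scale",
    "CTAS": "Canadian Triage and Acuity Scale",
    "MTS": "Manchester Triage System",
    "ESI": "Emergency Severity Index",
    "SET": "Spanish Triage System"
  },
  "ranking": [
    "guidelines",
    "ease_of_use",
    "ease_of_implementation",
    "ease_of_evaluation"
  ],
  "answers": [
    {
      "pair": [
        "guidelines",
        "ease_of_evaluation"
      ],
      "answer": "b"
    },
    {
      "pair": [
        "guidelines",
        "ease_of_use"
      ],
      "answer": "b"
    },
    {
      "pair": [
        "guidelines",
        "ease_of_use"
      ],
      "answer": "a"
    },
    {
      "pair": [
        "ease_of_use",
        "ease_of_implementation"
      ],
      "answer": "b"
    },
    {
      "pair": [
        "ease_of_implementation",
        "ease_of_evaluation"
      ],
      "answer": "indifferent"
    },
    {
      "pair": [
        "ease_of_use",
        "ease_of_implementation"
      ],
      "answer": "a"
    },
    {
      "pair": [
        "guidelines",
        "ease_of_use"
      ],
      "answer": "b"
    }
  ]
}
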
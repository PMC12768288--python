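{
  "description": "Synthetic stand-in fixture in the pipeline's selected-feature export dialect: a published 15-feature image selection for a 7-variety mung bean study, used here only to validate the export format (count and membership in the 43-feature name set).",
  "feature_names": [
    "perimeter",
    "area",
    "long axis length",
    "short axis length",
    "grey scale variance product function",
    "vollath function",
    "R-mean in RGB space",
    "G-mean in RGB space",
    "R-variance in RGB space",
    "H-mean in HSV space",
    "V-mean in HSV space",
    "V-variance in HSV space",
    "L-mean in LAB space",
    "A-mean in LAB space",
    "A-variance in LAB space"
  ]
}
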
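{
  "description": "Synthetic stand-in fixture in the pipeline's selected-feature export dialect: a published 44-wavenumber Raman selection for a 7-variety mung bean study, used here only to validate the export format (counts, grid membership, naming).",
  "wavenumbers_cm1": [486, 504, 506, 616, 626, 630, 640, 672, 684, 788, 878, 924, 928, 934, 968, 970, 976, 990, 994, 1012, 1140, 1150, 1338, 1342, 1344, 1352, 1356, 1444, 1446, 1484, 1492, 1500, 1506, 1518, 1524, 1590, 1592, 1714, 1716, 1722, 1728, 1732, 1770, 1772]
}
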
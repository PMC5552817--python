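{
  "description": "Published effective-wavelength selections (nm) for the reference kiwifruit dataset, by attribute and selector. Shipped for comparison/plotting only: the underlying spectra are not deposited, so these lists are a reference fixture, not a test oracle.",
  "version": 1,
  "firmness": {
    "spectral_range_nm": [450, 1000],
    "BW": [450, 555, 677, 732, 821, 843, 969],
    "SPA": [555, 1000, 638, 503, 452, 700, 822],
    "GAPLS": [958, 959, 960, 956, 916, 620, 621, 909]
  },
  "ssc": {
    "spectral_range_nm": [450, 1000],
    "BW": [489, 522, 555, 584, 626, 662, 685, 704, 736, 776, 832, 912, 952, 998],
    "SPA": [987, 960, 487, 496, 737, 814, 450, 945, 912, 643, 558, 522, 451, 692],
    "GAPLS": [877, 879, 958, 956, 880, 903, 876, 910, 905, 902, 955, 469, 909, 911, 959, 470, 976, 977, 690, 974, 468, 689, 828, 681, 691, 804, 965]
  },
  "ph": {
    "spectral_range_nm": [951, 1670],
    "BW": [1103, 1210, 1365, 1419, 1622, 1656],
    "SPA": [1659, 1670, 1298, 1133, 999],
    "GAPLS": [1670, 1649, 1646, 1653, 1666, 1642, 1656, 1639, 1632, 1636, 1629, 1029]
  }
}
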
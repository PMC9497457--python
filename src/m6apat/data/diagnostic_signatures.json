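{
  "m6a_regulator_signature": [
    "METTL16", "RBM15B", "KIAA1429", "CBLL1", "ALKBH5", "ALKBH1", "YTHDC2",
    "YTHDF3", "IGF2BP1", "IGF2BP2", "IGF2BP3", "FMR1", "LRPPRC", "ELAVL1"
  ],
  "lncrna_signature": [
    "ZNF582-AS1", "ZNF503-AS2", "UBL7-AS1", "TTTY5", "PRKAG2-AS1",
    "LINC01007", "LINC00424", "ADARB2-AS1"
  ]
}
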
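{
  "pathways": {
    "1": {
      "name": "Sphingolipid metabolism",
      "members": ["HMDB0011773", "HMDB0000277", "HMDB0000224", "HMDB0000269"]
    },
    "2": {
      "name": "Taurine and hypotaurine metabolism",
      "members": ["HMDB0000965", "HMDB0000251"]
    },
    "3": {
      "name": "Nitrogen metabolism",
      "members": ["HMDB0000148"]
    },
    "4": {
      "name": "Cysteine and methionine metabolism",
      "members": ["HMDB0000192", "HMDB0005765"]
    },
    "5": {
      "name": "Glycerophospholipid metabolism",
      "members": ["HMDB0000224", "HMDB0000086"]
    }
  },
  "background_size": 100
}
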
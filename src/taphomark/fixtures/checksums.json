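{
  "table1": "2b1dad47028d87114c7f9a8a4bbc8395679e6bfefbf00c699a9f5873b0d93f7f",
  "table3": "41928662e6eac7535d24b0f0147f4fa1af14f67bdd6759491f551ccf39fc20a7",
  "table4": "18202347c3a031ceea50c08b14b032b6392215c93b633ee54677dce3a89352ce",
  "table6": "47a8a7038ea9495f4abb83808b9be69a744efdca3c66ffc724de6ce913f4a89f"
}
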
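{
 "_comment": "Synthetic hand-curated miniature of a central-carbon reaction network for tests and examples. Compounds are metabolites, edges are reactions directed substrate->product, gene IDs are KO-style ortholog labels.",
 "compounds": [
  "lactose", "glucose", "galactose", "g6p", "f6p", "fbp", "g3p", "dhap",
  "glycerol", "pyruvate", "accoa", "citrate", "akg", "succinate", "malate",
  "oaa"
 ],
 "reactions": [
  {"id": "R01", "substrate": "lactose", "product": "glucose", "genes": ["K00001", "K00002"]},
  {"id": "R02", "substrate": "lactose", "product": "galactose", "genes": ["K00001"]},
  {"id": "R03", "substrate": "galactose", "product": "g6p", "genes": ["K00003"]},
  {"id": "R04", "substrate": "glucose", "product": "g6p", "genes": ["K00004"]},
  {"id": "R05", "substrate": "g6p", "product": "f6p", "genes": ["K00005"]},
  {"id": "R06", "substrate": "f6p", "product": "fbp", "genes": ["K00006"]},
  {"id": "R07", "substrate": "fbp", "product": "g3p", "genes": ["K00007"]},
  {"id": "R08", "substrate": "fbp", "product": "dhap", "genes": ["K00007"]},
  {"id": "R09", "substrate": "dhap", "product": "g3p", "genes": ["K00008"]},
  {"id": "R10", "substrate": "g3p", "product": "pyruvate", "genes": ["K00009", "K00010"]},
  {"id": "R11", "substrate": "glycerol", "product": "dhap", "genes": ["K00011", "K00012"]},
  {"id": "R12", "substrate": "pyruvate", "product": "accoa", "genes": ["K00013"]},
  {"id": "R13", "substrate": "accoa", "product": "citrate", "genes": ["K00014"]},
  {"id": "R14", "substrate": "citrate", "product": "akg", "genes": ["K00015"]},
  {"id": "R15", "substrate": "akg", "product": "succinate", "genes": ["K00016"]},
  {"id": "R16", "substrate": "succinate", "product": "malate", "genes": ["K00017"]},
  {"id": "R17", "substrate": "malate", "product": "oaa", "genes": ["K00018"]},
  {"id": "R18", "substrate": "oaa", "product": "pyruvate", "genes": ["K00019"]},
  {"id": "R19", "substrate": "g6p", "product": "glucose", "genes": ["K00020"]}
 ],
 "pathways": {
  "glycolysis_gluconeogenesis": {
   "compounds": ["glucose", "g6p", "f6p", "fbp", "g3p", "dhap", "pyruvate"],
   "genes": ["K00004", "K00005", "K00006", "K00007", "K00008", "K00009", "K00010", "K00020"]
  },
  "galactose_metabolism": {
   "compounds": ["lactose", "galactose", "glucose", "g6p"],
   "genes": ["K00001", "K00002", "K00003", "K00004"]
  },
  "tca_cycle": {
   "compounds": ["pyruvate", "accoa", "citrate", "akg", "succinate", "malate", "oaa"],
   "genes": ["K00013", "K00014", "K00015", "K00016", "K00017", "K00018", "K00019"]
  }
 },
 "destinations": ["g6p", "f6p", "fbp", "g3p", "pyruvate"]
}
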
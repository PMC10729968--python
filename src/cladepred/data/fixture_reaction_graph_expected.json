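{
 "_comment": "Hand-derived selections on the synthetic fixture graph. 'paths' entries are the union over the top-3 shortest loopless paths to any destination compound, ties broken by lexicographic compound sequence. Derivations: lactose directed paths = [lactose,glucose,g6p] (R01+R04), [lactose,galactose,g6p] (R02+R03), [lactose,galactose,g6p,f6p] (R02+R03+R05); undirected additionally unions R19 on the glucose-g6p hop; glycerol has only two loopless paths to destinations ([glycerol,dhap,g3p], [glycerol,dhap,g3p,pyruvate]) so both are used; glucose paths = [glucose,g6p], [glucose,g6p,f6p], [glucose,g6p,f6p,fbp].",
 "lactose": {
  "pathways": ["K00001", "K00002", "K00003", "K00004"],
  "reactions": ["K00001", "K00002"],
  "paths_directed": ["K00001", "K00002", "K00003", "K00004", "K00005"],
  "paths_undirected": ["K00001", "K00002", "K00003", "K00004", "K00005", "K00020"]
 },
 "glycerol": {
  "pathways": [],
  "reactions": ["K00011", "K00012"],
  "paths_directed": ["K00008", "K00009", "K00010", "K00011", "K00012"]
 },
 "glucose": {
  "pathways": ["K00001", "K00002", "K00003", "K00004", "K00005", "K00006", "K00007", "K00008", "K00009", "K00010", "K00020"],
  "reactions": ["K00001", "K00002", "K00004", "K00020"],
  "paths_directed": ["K00004", "K00005", "K00006"]
 }
}
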
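{
  "concepts": {
    "WhiteHouse": ["white house", "washington", "dc", "president", "d. palmer", "palmer"],
    "CIA": ["cia", "fbi", "dhs", "ctu", "chloe"],
    "sacrifice": ["sacrifice", "hostage", "exchange", "trade"],
    "handcuff": ["handcuff", "handcuffs", "ties", "bindings", "restraints", "chains"],
    "J.Bauer": ["j. bauer", "bauer", "jack", "main character", "agent"],
    "B.Buchanan": ["b. buchanan", "buchanan", "bill"],
    "A.Fayed": ["a. fayed", "fayed", "terrorist leader"],
    "A.Amar": ["a. amar", "amar", "son", "kid"]
  },
  "characters": {
    "A.Amar": "A.Amar",
    "A.Fayed": "A.Fayed",
    "J.Bauer": "J.Bauer",
    "K.Hayes": "WhiteHouse",
    "T.Lennox": "WhiteHouse",
    "W.Palmer": "WhiteHouse",
    "C.OBrian": "CIA",
    "N.Yassir": "CIA",
    "M.OBrian": "CIA",
    "M.Pressman": "CIA"
  }
}
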
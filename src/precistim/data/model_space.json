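{
  "nodes": ["IPL", "rPFC", "DLPFC", "SFG"],
  "inputs": ["stim", "regular", "different"],
  "common": {
    "a_edges": [["IPL", "rPFC"], ["IPL", "DLPFC"], ["DLPFC", "IPL"]],
    "b_edges": {
      "regular": [["IPL", "rPFC"]],
      "different": [["IPL", "DLPFC"]]
    },
    "c_targets": {"stim": ["IPL"]}
  },
  "models": {
    "Diamond": {
      "a_edges": [["rPFC", "SFG"], ["DLPFC", "SFG"]],
      "b_edges": {},
      "d_edges": []
    },
    "Fork": {
      "a_edges": [["IPL", "SFG"]],
      "b_edges": {
        "regular": [["IPL", "SFG"]],
        "different": [["IPL", "SFG"]]
      },
      "d_edges": []
    },
    "Legs1": {
      "a_edges": [["DLPFC", "SFG"]],
      "b_edges": {"regular": [["DLPFC", "SFG"]]},
      "d_edges": []
    },
    "Legs2": {
      "a_edges": [["rPFC", "SFG"]],
      "b_edges": {"different": [["rPFC", "SFG"]]},
      "d_edges": []
    },
    "Stork1": {
      "a_edges": [["DLPFC", "SFG"]],
      "b_edges": {},
      "d_edges": [{"gate": "rPFC", "edge": ["DLPFC", "SFG"]}]
    },
    "Stork2": {
      "a_edges": [["rPFC", "SFG"]],
      "b_edges": {},
      "d_edges": [{"gate": "DLPFC", "edge": ["rPFC", "SFG"]}]
    },
    "Stork3": {
      "a_edges": [["rPFC", "SFG"], ["DLPFC", "SFG"]],
      "b_edges": {},
      "d_edges": [
        {"gate": "rPFC", "edge": ["DLPFC", "SFG"]},
        {"gate": "DLPFC", "edge": ["rPFC", "SFG"]}
      ]
    }
  }
}
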
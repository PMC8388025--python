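{
 "metabolites": [
  {
   "id": "A",
   "compartment": "c"
  },
  {
   "id": "B",
   "compartment": "c"
  },
  {
   "id": "C",
   "compartment": "c"
  },
  {
   "id": "P",
   "compartment": "c"
  }
 ],
 "reactions": [
  {
   "id": "R_up",
   "stoichiometry": {
    "A": 1.0
   },
   "lb": 0.0,
   "ub": 10.0,
   "gpr": null
  },
  {
   "id": "R1",
   "stoichiometry": {
    "A": -1.0,
    "B": 1.0
   },
   "lb": 0.0,
   "ub": 10.0,
   "gpr": "g1"
  },
  {
   "id": "R2",
   "stoichiometry": {
    "A": -1.0,
    "C": 1.0
   },
   "lb": 0.0,
   "ub": 10.0,
   "gpr": "g2"
  },
  {
   "id": "R3",
   "stoichiometry": {
    "B": -1.0,
    "P": 1.0
   },
   "lb": 0.0,
   "ub": 10.0,
   "gpr": "g3 or (g1 and g4)"
  },
  {
   "id": "R_biomass",
   "stoichiometry": {
    "B": -1.0,
    "C": -1.0
   },
   "lb": 0.0,
   "ub": 10.0,
   "gpr": null
  },
  {
   "id": "EX_P",
   "stoichiometry": {
    "P": -1.0
   },
   "lb": 0.0,
   "ub": 10.0,
   "gpr": null
  }
 ],
 "genes": [
  "g1",
  "g2",
  "g3",
  "g4"
 ],
 "objective": "R_biomass"
}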
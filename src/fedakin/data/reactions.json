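{
 "species": [
  "DA",
  "DA_rad",
  "DAQ",
  "DAL",
  "DAC",
  "DecayProducts",
  "O2",
  "O2_rad",
  "H2O2",
  "OH_rad",
  "FeII",
  "FeIII",
  "AFO",
  "FeIIDA",
  "FeIIIDA",
  "FeIIIDA2"
 ],
 "ph_labels": [
  6.5,
  7.0,
  7.4
 ],
 "reactions": [
  {
   "id": 1,
   "reactants": [
    "DA",
    "O2"
   ],
   "products": [
    "O2_rad",
    "DA_rad"
   ],
   "rate_constants": {
    "6.5": 0.00394,
    "7.0": 0.00422,
    "7.4": 0.00824
   }
  },
  {
   "id": 2,
   "reactants": [
    "DA_rad",
    "O2"
   ],
   "products": [
    "O2_rad",
    "DAQ"
   ],
   "rate_constants": {
    "6.5": 2950.0,
    "7.0": 2950.0,
    "7.4": 2950.0
   },
   "reverse_rate_constants": {
    "6.5": 1000000000.0,
    "7.0": 1000000000.0,
    "7.4": 1000000000.0
   }
  },
  {
   "id": 3,
   "reactants": [
    "DA_rad",
    "DA_rad"
   ],
   "products": [
    "DA",
    "DAQ"
   ],
   "rate_constants": {
    "6.5": 235000000.0,
    "7.0": 235000000.0,
    "7.4": 235000000.0
   }
  },
  {
   "id": 4,
   "reactants": [
    "DAQ"
   ],
   "products": [
    "DAL"
   ],
   "rate_constants": {
    "6.5": 0.0123,
    "7.0": 1.0,
    "7.4": 4.45
   }
  },
  {
   "id": 5,
   "reactants": [
    "DAL",
    "DAQ"
   ],
   "products": [
    "DA",
    "DAC"
   ],
   "rate_constants": {
    "6.5": 5300000.0,
    "7.0": 5300000.0,
    "7.4": 5300000.0
   }
  },
  {
   "id": 6,
   "reactants": [
    "DAL",
    "O2"
   ],
   "products": [
    "DAC",
    "H2O2"
   ],
   "rate_constants": {
    "6.5": 1.17,
    "7.0": 1.31,
    "7.4": 5.12
   }
  },
  {
   "id": 7,
   "reactants": [
    "O2_rad",
    "O2_rad"
   ],
   "products": [
    "H2O2",
    "O2"
   ],
   "rate_constants": {
    "6.5": 1900000.0,
    "7.0": 600000.0,
    "7.4": 190000.0
   }
  },
  {
   "id": 8,
   "reactants": [
    "DA_rad",
    "O2_rad"
   ],
   "products": [
    "DAQ",
    "H2O2"
   ],
   "rate_constants": {
    "6.5": 8270000000.0,
    "7.0": 8270000000.0,
    "7.4": 8270000000.0
   }
  },
  {
   "id": 9,
   "reactants": [
    "DAC"
   ],
   "products": [
    "DecayProducts"
   ],
   "rate_constants": {
    "6.5": 1.2e-06,
    "7.0": 8e-05,
    "7.4": 0.0004
   }
  },
  {
   "id": 10,
   "reactants": [
    "FeIII",
    "FeIII"
   ],
   "products": [
    "AFO",
    "AFO"
   ],
   "rate_constants": {
    "6.5": 1000000.0,
    "7.0": 3400000.0,
    "7.4": 5000000.0
   }
  },
  {
   "id": 11,
   "reactants": [
    "AFO",
    "DA"
   ],
   "products": [
    "FeIIIDA"
   ],
   "rate_constants": {
    "6.5": 0.599,
    "7.0": 2.3,
    "7.4": 2.34
   }
  },
  {
   "id": 12,
   "reactants": [
    "AFO",
    "DA"
   ],
   "products": [
    "FeII",
    "DA_rad"
   ],
   "rate_constants": {
    "6.5": 0.008,
    "7.0": 0.3,
    "7.4": 0.6
   }
  },
  {
   "id": 13,
   "reactants": [
    "FeIII",
    "DA"
   ],
   "products": [
    "FeIIIDA"
   ],
   "rate_constants": {
    "6.5": 87000.0,
    "7.0": 209000.0,
    "7.4": 415000.0
   },
   "reverse_rate_constants": {
    "6.5": 1.45,
    "7.0": 0.969,
    "7.4": 0.463
   }
  },
  {
   "id": 14,
   "reactants": [
    "FeIIIDA",
    "DA"
   ],
   "products": [
    "FeIIIDA2"
   ],
   "rate_constants": {
    "6.5": 450000.0,
    "7.0": 450000.0,
    "7.4": 450000.0
   },
   "reverse_rate_constants": {
    "6.5": 0.000337,
    "7.0": 0.000286,
    "7.4": 0.000259
   }
  },
  {
   "id": 15,
   "reactants": [
    "FeIIIDA",
    "O2_rad"
   ],
   "products": [
    "FeIIDA",
    "O2"
   ],
   "rate_constants": {
    "6.5": 150000000.0,
    "7.0": 150000000.0,
    "7.4": 150000000.0
   }
  },
  {
   "id": 16,
   "reactants": [
    "FeIIIDA"
   ],
   "products": [
    "FeII",
    "DA_rad"
   ],
   "rate_constants": {
    "6.5": 0.23,
    "7.0": 0.23,
    "7.4": 0.23
   }
  },
  {
   "id": 17,
   "reactants": [
    "FeIIIDA2"
   ],
   "products": [
    "FeII",
    "DA",
    "DA_rad"
   ],
   "rate_constants": {
    "6.5": 7.26e-05,
    "7.0": 7.26e-05,
    "7.4": 7.26e-05
   }
  },
  {
   "id": 18,
   "reactants": [
    "FeIII",
    "O2_rad"
   ],
   "products": [
    "FeII",
    "O2"
   ],
   "rate_constants": {
    "6.5": 150000000.0,
    "7.0": 150000000.0,
    "7.4": 150000000.0
   }
  },
  {
   "id": 19,
   "reactants": [
    "AFO",
    "O2_rad"
   ],
   "products": [
    "FeII",
    "O2"
   ],
   "rate_constants": {
    "6.5": 48400.0,
    "7.0": 370000.0,
    "7.4": 370000.0
   }
  },
  {
   "id": 20,
   "reactants": [
    "FeIII",
    "DA_rad"
   ],
   "products": [
    "FeII",
    "DAQ"
   ],
   "rate_constants": {
    "6.5": 9120000000.0,
    "7.0": 9120000000.0,
    "7.4": 9120000000.0
   }
  },
  {
   "id": 21,
   "reactants": [
    "FeII",
    "O2"
   ],
   "products": [
    "FeIII",
    "O2_rad"
   ],
   "rate_constants": {
    "6.5": 0.0209,
    "7.0": 0.0959,
    "7.4": 0.77
   }
  },
  {
   "id": 22,
   "reactants": [
    "FeII",
    "O2_rad"
   ],
   "products": [
    "FeIII",
    "H2O2"
   ],
   "rate_constants": {
    "6.5": 10000000.0,
    "7.0": 10000000.0,
    "7.4": 10000000.0
   }
  },
  {
   "id": 23,
   "reactants": [
    "FeII",
    "H2O2"
   ],
   "products": [
    "FeIII",
    "OH_rad"
   ],
   "rate_constants": {
    "6.5": 1720.0,
    "7.0": 4790.0,
    "7.4": 13300.0
   }
  },
  {
   "id": 24,
   "reactants": [
    "FeII",
    "DA"
   ],
   "products": [
    "FeIIDA"
   ],
   "rate_constants": {
    "6.5": 700.0,
    "7.0": 720.0,
    "7.4": 750.0
   },
   "reverse_rate_constants": {
    "6.5": 0.0102,
    "7.0": 0.0092,
    "7.4": 0.0016
   }
  },
  {
   "id": 25,
   "reactants": [
    "FeIIDA",
    "O2"
   ],
   "products": [
    "FeIIIDA",
    "O2_rad"
   ],
   "rate_constants": {
    "6.5": 3.32,
    "7.0": 19.0,
    "7.4": 145.0
   }
  },
  {
   "id": 26,
   "reactants": [
    "FeIIDA",
    "H2O2"
   ],
   "products": [
    "FeIIIDA",
    "OH_rad"
   ],
   "rate_constants": {
    "6.5": 1720.0,
    "7.0": 4790.0,
    "7.4": 13300.0
   }
  },
  {
   "id": 27,
   "reactants": [
    "FeIIDA",
    "O2_rad"
   ],
   "products": [
    "FeIIIDA",
    "H2O2"
   ],
   "rate_constants": {
    "6.5": 10000000.0,
    "7.0": 10000000.0,
    "7.4": 10000000.0
   }
  },
  {
   "id": 28,
   "reactants": [
    "FeIIDA",
    "DA_rad"
   ],
   "products": [
    "FeIIIDA",
    "DA"
   ],
   "rate_constants": {
    "6.5": 192000.0,
    "7.0": 192000.0,
    "7.4": 192000.0
   }
  },
  {
   "id": 29,
   "reactants": [
    "FeII",
    "DA_rad"
   ],
   "products": [
    "FeIII",
    "DA"
   ],
   "rate_constants": {
    "6.5": 192000.0,
    "7.0": 192000.0,
    "7.4": 192000.0
   }
  }
 ]
}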
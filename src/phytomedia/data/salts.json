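{
  "NH4NO3":        {"formula": "NH4NO3",            "molar_mass": 80.04,  "ion_yield": {"NH4+": 1, "NO3-": 1}},
  "KNO3":          {"formula": "KNO3",              "molar_mass": 101.10, "ion_yield": {"K+": 1, "NO3-": 1}},
  "CaCl2.2H2O":    {"formula": "CaCl2.2H2O",        "molar_mass": 147.02, "ion_yield": {"Ca2+": 1, "Cl-": 2}},
  "MgSO4.7H2O":    {"formula": "MgSO4.7H2O",        "molar_mass": 246.48, "ion_yield": {"Mg2+": 1, "SO42-": 1}},
  "KH2PO4":        {"formula": "KH2PO4",            "molar_mass": 136.09, "ion_yield": {"K+": 1, "PO43-": 1}},
  "MnSO4.4H2O":    {"formula": "MnSO4.4H2O",        "molar_mass": 223.06, "ion_yield": {"Mn2+": 1, "SO42-": 1}},
  "ZnSO4.7H2O":    {"formula": "ZnSO4.7H2O",        "molar_mass": 287.56, "ion_yield": {"Zn2+": 1, "SO42-": 1}},
  "H3BO3":         {"formula": "H3BO3",             "molar_mass": 61.83,  "ion_yield": {"BO3-": 1}},
  "KI":            {"formula": "KI",                "molar_mass": 166.00, "ion_yield": {"K+": 1, "I-": 1}},
  "CuSO4.5H2O":    {"formula": "CuSO4.5H2O",        "molar_mass": 249.69, "ion_yield": {"Cu2+": 1, "SO42-": 1}},
  "Na2MoO4.2H2O":  {"formula": "Na2MoO4.2H2O",      "molar_mass": 241.95, "ion_yield": {"MoO22-": 1, "Na+": 2}},
  "CoCl2.6H2O":    {"formula": "CoCl2.6H2O",        "molar_mass": 237.93, "ion_yield": {"Co2+": 1, "Cl-": 2}},
  "FeSO4.7H2O":    {"formula": "FeSO4.7H2O",        "molar_mass": 278.01, "ion_yield": {"Fe2+": 1, "SO42-": 1}},
  "Na2EDTA.2H2O":  {"formula": "Na2EDTA.2H2O",      "molar_mass": 372.24, "ion_yield": {"Na+": 2, "EDTA-": 1}},
  "(NH4)2SO4":     {"formula": "(NH4)2SO4",         "molar_mass": 132.14, "ion_yield": {"NH4+": 2, "SO42-": 1}},
  "Ca(NO3)2.4H2O": {"formula": "Ca(NO3)2.4H2O",     "molar_mass": 236.15, "ion_yield": {"Ca2+": 1, "NO3-": 2}},
  "NaH2PO4.H2O":   {"formula": "NaH2PO4.H2O",       "molar_mass": 137.99, "ion_yield": {"Na+": 1, "PO43-": 1}}
}
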
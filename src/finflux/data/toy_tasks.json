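[
 {
  "id": "synthesize_arg_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "arg_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "infeasible"
 },
 {
  "id": "synthesize_his_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "his_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "infeasible"
 },
 {
  "id": "synthesize_ile_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "ile_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "infeasible"
 },
 {
  "id": "synthesize_leu_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "leu_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "infeasible"
 },
 {
  "id": "synthesize_lys_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "lys_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "infeasible"
 },
 {
  "id": "synthesize_met_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "met_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "infeasible"
 },
 {
  "id": "synthesize_phe_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "phe_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "infeasible"
 },
 {
  "id": "synthesize_thr_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "thr_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "infeasible"
 },
 {
  "id": "synthesize_trp_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "trp_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "infeasible"
 },
 {
  "id": "synthesize_val_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "val_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "infeasible"
 },
 {
  "id": "synthesize_ala_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "ala_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "feasible"
 },
 {
  "id": "synthesize_asp_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "asp_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "feasible"
 },
 {
  "id": "synthesize_glu_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "glu_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "feasible"
 },
 {
  "id": "synthesize_gly_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "gly_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "feasible"
 },
 {
  "id": "synthesize_ser_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "ser_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "feasible"
 },
 {
  "id": "synthesize_pro_de_novo",
  "system": "amino acid synthesis",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "o2",
    100
   ],
   [
    "pi",
    10
   ]
  ],
  "secretions": [
   [
    "pro_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "feasible"
 },
 {
  "id": "membrane_lipid_synthesis",
  "system": "lipid metabolism",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "chol",
    1
   ],
   [
    "pi",
    10
   ],
   [
    "o2",
    100
   ]
  ],
  "secretions": [
   [
    "pc_c",
    0.05
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "feasible"
 },
 {
  "id": "nucleotide_synthesis",
  "system": "nucleotide metabolism",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "nh3",
    10
   ],
   [
    "pi",
    10
   ],
   [
    "o2",
    100
   ]
  ],
  "secretions": [
   [
    "ntp_c",
    0.05
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "feasible"
 },
 {
  "id": "glycogen_storage",
  "system": "carbohydrate metabolism",
  "uptakes": [
   [
    "glc",
    10
   ],
   [
    "o2",
    100
   ]
  ],
  "secretions": [
   [
    "glycg_c",
    0.1
   ],
   [
    "co2",
    0.0
   ]
  ],
  "expected": "feasible"
 },
 {
  "id": "urea_excretion_from_amino_acids",
  "system": "nitrogen disposal",
  "uptakes": [
   [
    "leu",
    5
   ],
   [
    "o2",
    100
   ]
  ],
  "secretions": [
   [
    "urea",
    0.01
   ],
   [
    "co2",
    0.0
   ],
   [
    "nh3",
    0.0
   ]
  ],
  "expected": "feasible"
 }
]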
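[
  "nasion",
  "pronasale",
  "subnasale",
  "gnathion",
  "endocanthion_l",
  "endocanthion_r",
  "exocanthion_l",
  "exocanthion_r",
  "palpebrale_superius_l",
  "palpebrale_superius_r",
  "palpebrale_inferius_l",
  "palpebrale_inferius_r",
  "alare_l",
  "alare_r",
  "alar_crest_l",
  "alar_crest_r",
  "cheilion_l",
  "cheilion_r",
  "crista_philtri_l",
  "crista_philtri_r",
  "tragion_l",
  "tragion_r",
  "otobasion_superius_l",
  "otobasion_superius_r",
  "otobasion_inferius_l",
  "otobasion_inferius_r",
  "preaurale_l",
  "preaurale_r",
  "zygion_l",
  "zygion_r",
  "frontotemporale_l",
  "frontotemporale_r",
  "gonion_l",
  "gonion_r"
]
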
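# Sepsis-related ICD-10 code lists, seeded from the GBD sepsis code
# groupings (Rudd et al., Lancet 2020).  Entries are dot-free prefixes:
# a 3-character prefix covers all its 4-character children, a 4-character
# entry matches only itself.  This file is configuration — edit it to match
# the code list in force for a given analysis; the loader validates
# structure and cross-list duplicates.
provenance: "seeded from the GBD sepsis ICD-10 groupings (Rudd et al. 2020)"
explicit:
  - A021   # Salmonella sepsis
  - A207   # septicemic plague
  - A217   # generalized tularemia
  - A227   # anthrax sepsis
  - A267   # erysipelothrix sepsis
  - A327   # listerial sepsis
  - A392   # acute meningococcemia
  - A393   # chronic meningococcemia
  - A394   # meningococcemia, unspecified
  - A40    # streptococcal sepsis
  - A41    # other sepsis
  - A427   # actinomycotic sepsis
  - A483   # toxic shock syndrome
  - B377   # candidal sepsis
  - O85    # puerperal sepsis
  - P36    # bacterial sepsis of newborn
  - R651   # SIRS of infectious origin with organ failure
  - R652   # severe sepsis
  - T814   # infection following a procedure
infection:
  - A09    # infectious gastroenteritis
  - A46    # erysipelas
  - A49    # bacterial infection, unspecified site
  - B99    # unspecified infectious disease
  - G00    # bacterial meningitis
  - I33    # acute and subacute endocarditis
  - J12    # viral pneumonia
  - J13    # pneumonia due to S. pneumoniae
  - J14    # pneumonia due to H. influenzae
  - J15    # bacterial pneumonia
  - J18    # pneumonia, organism unspecified
  - J69    # pneumonitis due to solids and liquids
  - K65    # peritonitis
  - K81    # cholecystitis
  - K83    # other diseases of biliary tract
  - L03    # cellulitis
  - M86    # osteomyelitis
  - N10    # acute pyelonephritis
  - N39    # urinary tract infection and other urinary disorders
organ_dysfunction:
  - D65    # disseminated intravascular coagulation
  - F05    # delirium
  - G931   # anoxic brain damage
  - I95    # hypotension
  - J96    # respiratory failure
  - K72    # hepatic failure
  - N17    # acute kidney failure
  - R57    # shock
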
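pt	soc
Headache	Nervous system disorders
Nausea	Gastrointestinal disorders
Fatigue	General disorders and administration site conditions
Diarrhoea	Gastrointestinal disorders
Rash	Skin and subcutaneous tissue disorders
Arthralgia	Musculoskeletal and connective tissue disorders
Pyrexia	General disorders and administration site conditions
Vomiting	Gastrointestinal disorders
Dizziness	Nervous system disorders
Pruritus	Skin and subcutaneous tissue disorders
Insomnia	Psychiatric disorders
Cough	Respiratory, thoracic and mediastinal disorders
Abdominal pain	Gastrointestinal disorders
Anxiety	Psychiatric disorders
Back pain	Musculoskeletal and connective tissue disorders
Dyspnoea	Respiratory, thoracic and mediastinal disorders
Constipation	Gastrointestinal disorders
Oedema peripheral	General disorders and administration site conditions
Acne	Skin and subcutaneous tissue disorders
Haematochezia	Gastrointestinal disorders
Nasopharyngitis	Infections and infestations
Flatulence	Gastrointestinal disorders
Herpes zoster	Infections and infestations
Frequent bowel movements	Gastrointestinal disorders
Blood cholesterol increased	Investigations
Pulmonary embolism	Respiratory, thoracic and mediastinal disorders
Product residue present	Investigations
Semen discolouration	Reproductive system and breast disorders
High density lipoprotein increased	Investigations
Acne cystic	Skin and subcutaneous tissue disorders
Lipids increased	Investigations
Gastric perforation	Gastrointestinal disorders
Malabsorption	Gastrointestinal disorders
Venous thrombosis limb	Vascular disorders
Genital herpes	Infections and infestations
Large intestinal haemorrhage	Gastrointestinal disorders
Appendicitis perforated	Infections and infestations
Large intestine infection	Infections and infestations
Proctitis	Gastrointestinal disorders
Low density lipoprotein increased	Investigations
Defaecation urgency	Gastrointestinal disorders
Eye oedema	Eye disorders
Adverse food reaction	General disorders and administration site conditions
Large intestine perforation	Gastrointestinal disorders
Mucous stools	Gastrointestinal disorders
Rosacea	Skin and subcutaneous tissue disorders
Portal vein thrombosis	Hepatobiliary disorders
Proctalgia	Gastrointestinal disorders
Gastric infection	Infections and infestations
Large intestine polyp	Gastrointestinal disorders
Gastrointestinal perforation	Gastrointestinal disorders
Cytomegalovirus colitis	Infections and infestations
Blood cholesterol abnormal	Investigations
Inflammatory marker increased	Investigations
Polyp	General disorders and administration site conditions
Herpes simplex	Infections and infestations
Clostridium difficile infection	Infections and infestations
Atypical pneumonia	Infections and infestations
Folliculitis	Infections and infestations
General symptom	General disorders and administration site conditions
Rectal cancer	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Diarrhoea haemorrhagic	Gastrointestinal disorders
Mean cell volume increased	Investigations
Embolism venous	Vascular disorders
Pulmonary thrombosis	Respiratory, thoracic and mediastinal disorders
Respiratory symptom	Respiratory, thoracic and mediastinal disorders
Blood triglycerides increased	Investigations
Herpes virus infection	Infections and infestations
Abdominal abscess	Infections and infestations
Gastrointestinal pain	Gastrointestinal disorders
Retinal detachment	Eye disorders
Respiratory disorder	Respiratory, thoracic and mediastinal disorders
Upper limb fracture	Injury, poisoning and procedural complications
Cataract	Eye disorders
Deep vein thrombosis	Vascular disorders
Bronchitis	Infections and infestations
Sepsis	Infections and infestations
Embolism	Vascular disorders
Colon cancer	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Malnutrition	Metabolism and nutrition disorders
Gastrointestinal infection	Infections and infestations
Platelet count increased	Investigations
Oral herpes	Infections and infestations
Diverticulitis	Infections and infestations
Basal cell carcinoma	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Cytomegalovirus infection	Infections and infestations
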
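cancer_type	system
Bladder	Tumor of urinary tract
Bone	Orthopedic tumor
Cervical	Gynecological tumor
Colorectal	Digestive tract cancer
Esophageal	Digestive tract cancer
Gastric	Digestive tract cancer
Leukemia	Hematological tumors
Liver	Digestive tract cancer
Lymphoma	Hematological tumors
Myeloma	Orthopedic tumor
Pancreatic	Digestive tract cancer
Prostate	Tumor of urinary tract
Renal	Tumor of urinary tract
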
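oncotree_code	label	ncit_code
MEL	Melanoma	C3224
UM	Uveal Melanoma	C7712
BCC	Basal Cell Carcinoma	C2921
CSCC	Cutaneous Squamous Cell Carcinoma	C4819
LUAD	Lung Adenocarcinoma	C3512
LUSC	Lung Squamous Cell Carcinoma	C3493
NSCLC	Non-Small Cell Lung Cancer	C2926
SCLC	Small Cell Lung Cancer	C4917
BRCA	Invasive Breast Carcinoma	C9245
IDC	Breast Invasive Ductal Carcinoma	C4194
ILC	Breast Invasive Lobular Carcinoma	C4195
COAD	Colon Adenocarcinoma	C4349
READ	Rectal Adenocarcinoma	C9005
STAD	Stomach Adenocarcinoma	C4004
HCC	Hepatocellular Carcinoma	C3099
CHOL	Cholangiocarcinoma	C4436
PAAD	Pancreatic Adenocarcinoma	C8294
PRAD	Prostate Adenocarcinoma	C2919
BLCA	Bladder Urothelial Carcinoma	C4912
CCRCC	Renal Clear Cell Carcinoma	C4033
PRCC	Papillary Renal Cell Carcinoma	C6975
UCEC	Endometrial Carcinoma	C2916
CESC	Cervical Squamous Cell Carcinoma	C27676
SOC	Serous Ovarian Cancer	C7550
GBM	Glioblastoma Multiforme	C3058
MNG	Meningioma	C3230
MBL	Medulloblastoma	C3222
EPN	Ependymoma	C3017
RGNT	rosette-forming glioneuronal tumor	C97362
ASTR	Astrocytoma	C60781
THPA	Papillary Thyroid Cancer	C4035
ATC	Anaplastic Thyroid Cancer	C3878
MTC	Medullary Thyroid Cancer	C3879
HNSC	Head and Neck Squamous Cell Carcinoma	C34447
OS	Osteosarcoma	C9145
ES	Ewing Sarcoma	C4817
RMS	Rhabdomyosarcoma	C3359
LMS	Leiomyosarcoma	C3158
GIST	Gastrointestinal Stromal Tumor	C3868
NBL	Neuroblastoma	C3270
WT	Wilms Tumor	C3267
RB	Retinoblastoma	C7541
AML	Acute Myeloid Leukemia	C3171
ALL	Acute Lymphoblastic Leukemia	C3167
CLL	Chronic Lymphocytic Leukemia	C3163
CML	Chronic Myelogenous Leukemia	C3174
DLBCL	Diffuse Large B-Cell Lymphoma	C8851
HL	Hodgkin Lymphoma	C9357
MDS	Myelodysplastic Syndromes	C3247
MM	Multiple Myeloma	C3242
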
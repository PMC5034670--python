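category_id	name
tuberculosis	Tuberculosis
hiv	HIV/AIDS
common_infectious	Diarrheal diseases
common_infectious	Typhoid and paratyphoid fevers
common_infectious	Lower respiratory infections
common_infectious	Upper respiratory infections
common_infectious	Otitis media
common_infectious	Meningitis
common_infectious	Encephalitis
common_infectious	Diphtheria
common_infectious	Whooping cough
common_infectious	Tetanus
common_infectious	Measles
common_infectious	Varicella
malaria	Malaria
neglected_tropical	Chagas disease
neglected_tropical	Leishmaniasis
neglected_tropical	African trypanosomiasis
neglected_tropical	Schistosomiasis
neglected_tropical	Cysticercosis
neglected_tropical	Echinococcosis
neglected_tropical	Lymphatic filariasis
neglected_tropical	Onchocerciasis
neglected_tropical	Trachoma
neglected_tropical	Dengue
neglected_tropical	Yellow fever
neglected_tropical	Rabies
neglected_tropical	Food-borne trematodiases
neglected_tropical	Intestinal nematode infections
neglected_tropical	Other neglected tropical diseases
maternal	Maternal hemorrhage
maternal	Maternal sepsis
maternal	Hypertensive disorders of pregnancy
maternal	Obstructed labor
maternal	Abortion
maternal	Other maternal disorders
neonatal	Preterm birth complications
neonatal	Neonatal encephalopathy
neonatal	Sepsis and other infectious disorders of the newborn baby
neonatal	Other neonatal disorders
nutritional	Protein-energy malnutrition
nutritional	Iodine deficiency
nutritional	Vitamin A deficiency
nutritional	Iron-deficiency anemia
nutritional	Other nutritional deficiencies
std	Syphilis
std	Sexually transmitted chlamydial diseases
std	Gonococcal infection
std	Trichomoniasis
std	Other sexually transmitted diseases
hepatitis	Acute hepatitis A
hepatitis	Acute hepatitis B
hepatitis	Acute hepatitis C
hepatitis	Acute hepatitis E
leprosy	Leprosy
neoplasms	Esophageal cancer
neoplasms	Stomach cancer
neoplasms	Liver cancer
neoplasms	Larynx cancer
neoplasms	Trachea, bronchus, and lung cancers
neoplasms	Breast cancer
neoplasms	Cervical cancer
neoplasms	Uterine cancer
neoplasms	Prostate cancer
neoplasms	Colon and rectum cancers
neoplasms	Mouth cancer
neoplasms	Nasopharynx cancer
neoplasms	Cancer of other part of pharynx and oropharynx
neoplasms	Gallbladder and biliary tract cancer
neoplasms	Pancreatic cancer
neoplasms	Malignant melanoma of skin
neoplasms	Non-melanoma skin cancer
neoplasms	Ovarian cancer
neoplasms	Testicular cancer
neoplasms	Kidney and other urinary organ cancers
neoplasms	Bladder cancer
neoplasms	Brain and nervous system cancers
neoplasms	Thyroid cancer
neoplasms	Hodgkin's disease
neoplasms	Non-Hodgkin lymphoma
neoplasms	Multiple myeloma
neoplasms	Leukemia
neoplasms	Other neoplasms
cardiovascular	Rheumatic heart disease
cardiovascular	Ischemic heart disease
cardiovascular	Cerebrovascular disease
cardiovascular	Hypertensive heart disease
cardiovascular	Cardiomyopathy and myocarditis
cardiovascular	Atrial fibrillation and flutter
cardiovascular	Aortic aneurysm
cardiovascular	Peripheral vascular disease
cardiovascular	Endocarditis
cardiovascular	Other cardiovascular and circulatory diseases
chronic_respiratory	Chronic obstructive pulmonary disease
chronic_respiratory	Pneumoconiosis
chronic_respiratory	Asthma
chronic_respiratory	Interstitial lung disease and pulmonary sarcoidosis
chronic_respiratory	Other chronic respiratory diseases
cirrhosis	Cirrhosis of the liver
digestive	Peptic ulcer disease
digestive	Gastritis and duodenitis
digestive	Appendicitis
digestive	Paralytic ileus and intestinal obstruction without hernia
digestive	Inguinal or femoral hernia
digestive	Non-infective inflammatory bowel disease
digestive	Vascular disorders of intestine
digestive	Gall bladder and bile duct disease
digestive	Pancreatitis
digestive	Other digestive diseases
neurological	Alzheimer's disease and other dementias
neurological	Parkinson's disease
neurological	Epilepsy
neurological	Multiple sclerosis
neurological	Migraine
neurological	Tension-type headache
neurological	Other neurological disorders
mental	Schizophrenia
mental	Alcohol use disorders
mental	Drug use disorders
mental	Unipolar depressive disorders
mental	Bipolar affective disorder
mental	Anxiety disorders
mental	Eating disorders
mental	Pervasive development disorders
mental	Childhood behavioral disorders
mental	Idiopathic intellectual disability
mental	Other mental and behavioral disorders
diabetes_urinary	Diabetes mellitus
diabetes_urinary	Acute glomerulonephritis
diabetes_urinary	Chronic kidney diseases
diabetes_urinary	Urinary diseases and male infertility
gynecological	Uterine fibroids
gynecological	Polycystic ovarian syndrome
gynecological	Female infertility
gynecological	Endometriosis
gynecological	Genital prolapse
gynecological	Premenstrual syndrome
gynecological	Other gynecological diseases
hemoglobinopathies	Hemoglobinopathies and hemolytic anemias
hemoglobinopathies	Thalassemias
hemoglobinopathies	Sickle cell disorders
hemoglobinopathies	G6PD deficiency
hemoglobinopathies	Other hemoglobinopathies and hemolytic anemias
musculoskeletal	Rheumatoid arthritis
musculoskeletal	Osteoarthritis
musculoskeletal	Low back and neck pain
musculoskeletal	Gout
musculoskeletal	Other musculoskeletal disorders
congenital	Congenital anomalies
congenital	Neural tube defects
congenital	Congenital heart anomalies
congenital	Cleft lip and cleft palate
congenital	Down's syndrome
congenital	Other chromosomal abnormalities
congenital	Other congenital anomalies
skin	Eczema
skin	Psoriasis
skin	Cellulitis
skin	Abscess, impetigo, and other bacterial skin diseases
skin	Scabies
skin	Fungal skin diseases
skin	Viral skin diseases
skin	Acne vulgaris
skin	Alopecia areata
skin	Pruritus
skin	Urticaria
skin	Decubitus ulcer
skin	Other skin and subcutaneous diseases
sense_organ	Glaucoma
sense_organ	Cataracts
sense_organ	Macular degeneration
sense_organ	Refraction and accommodation disorders
sense_organ	Other hearing loss
sense_organ	Other vision loss
sense_organ	Other sense organ diseases
oral	Dental caries
oral	Periodontal disease
oral	Edentulism
sids	Sudden infant death syndrome
injuries	Transport injuries
injuries	Unintentional injuries other than transport injuries
injuries	Self-harm and interpersonal violence
injuries	Forces of nature, war, and legal intervention
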
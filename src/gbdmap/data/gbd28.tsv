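category_id	category_name	residual_flag	icd10_spec
tuberculosis	Tuberculosis	0	A15-A19.9
tuberculosis	Tuberculosis	0	B90-B90.9
tuberculosis	Tuberculosis	0	P37.0
hiv	HIV/AIDS	0	B20-B24.9
common_infectious	Diarrhea, lower respiratory infections, meningitis, and other common infectious diseases	0	A00-A09.9
common_infectious	Diarrhea, lower respiratory infections, meningitis, and other common infectious diseases	0	A33-A37.9
common_infectious	Diarrhea, lower respiratory infections, meningitis, and other common infectious diseases	0	B01-B01.9
common_infectious	Diarrhea, lower respiratory infections, meningitis, and other common infectious diseases	0	B05-B05.9
common_infectious	Diarrhea, lower respiratory infections, meningitis, and other common infectious diseases	0	G00-G05.9
common_infectious	Diarrhea, lower respiratory infections, meningitis, and other common infectious diseases	0	H65-H67.9
common_infectious	Diarrhea, lower respiratory infections, meningitis, and other common infectious diseases	0	J00-J06.9
common_infectious	Diarrhea, lower respiratory infections, meningitis, and other common infectious diseases	0	J09-J22.9
malaria	Malaria	0	B50-B54.9
neglected_tropical	Neglected tropical diseases excluding malaria	0	A71-A71.9
neglected_tropical	Neglected tropical diseases excluding malaria	0	A82-A82.9
neglected_tropical	Neglected tropical diseases excluding malaria	0	A90-A91.9
neglected_tropical	Neglected tropical diseases excluding malaria	0	A95-A95.9
neglected_tropical	Neglected tropical diseases excluding malaria	0	B55-B57.9
neglected_tropical	Neglected tropical diseases excluding malaria	0	B65-B83.9
neglected_tropical	Neglected tropical diseases excluding malaria	0	P37.3
maternal	Maternal disorders	0	O00-O99.9
neonatal	Neonatal disorders	0	P00-P36.9
neonatal	Neonatal disorders	0	P38-P96.9
nutritional	Nutritional deficiencies	0	D50-D53.9
nutritional	Nutritional deficiencies	0	E00-E02.9
nutritional	Nutritional deficiencies	0	E40-E64.9
std	Sexually transmitted diseases excluding HIV	0	A50-A64.9
hepatitis	Hepatitis	0	B15-B19.9
leprosy	Leprosy	0	A30-A30.9
neoplasms	Neoplasms	0	C00-C97.9
neoplasms	Neoplasms	0	D00-D48.9
cardiovascular	Cardiovascular and circulatory diseases	0	I00-I99.9
chronic_respiratory	Chronic respiratory diseases	0	J30-J99.9
cirrhosis	Cirrhosis of the liver	0	K70-K74.9
digestive	Digestive diseases (except cirrhosis)	0	K20-K69.9
digestive	Digestive diseases (except cirrhosis)	0	K75-K93.9
neurological	Neurological disorders	0	F00-F03.9
neurological	Neurological disorders	0	G10-G99.9
mental	Mental and behavioral disorders	0	F04-F99.9
diabetes_urinary	Diabetes, urinary diseases and male infertility	0	E10-E14.9
diabetes_urinary	Diabetes, urinary diseases and male infertility	0	N00-N51.9
gynecological	Gynecological diseases	0	N60-N98.9
hemoglobinopathies	Hemoglobinopathies and hemolytic anemias	0	D55-D64.9
musculoskeletal	Musculoskeletal disorders	0	M00-M99.9
congenital	Congenital anomalies	0	Q00-Q99.9
skin	Skin and subcutaneous diseases	0	L00-L99.9
sense_organ	Sense organ diseases	0	H00-H64.9
sense_organ	Sense organ diseases	0	H68-H95.9
oral	Oral disorders	0	K00-K14.9
sids	Sudden infant death syndrome	0	R95-R95.9
injuries	Injuries	0	S00-T98.9
injuries	Injuries	0	V01-Y98.9
other_infectious	Other infectious diseases	1	A20-A28.9
other_infectious	Other infectious diseases	1	A42-A49.9
other_infectious	Other infectious diseases	1	A65-A70.9
other_infectious	Other infectious diseases	1	A74-A81.9
other_infectious	Other infectious diseases	1	A92-A94.9
other_infectious	Other infectious diseases	1	A96-A99.9
other_infectious	Other infectious diseases	1	B00-B00.9
other_infectious	Other infectious diseases	1	B02-B04.9
other_infectious	Other infectious diseases	1	B06-B09.9
other_infectious	Other infectious diseases	1	B25-B49.9
other_infectious	Other infectious diseases	1	B85-B89.9
other_infectious	Other infectious diseases	1	B91-B99.9
other_endocrine	Other endocrine, nutritional, blood, and immune disorders	1	D65-D89.9
other_endocrine	Other endocrine, nutritional, blood, and immune disorders	1	E03-E07.9
other_endocrine	Other endocrine, nutritional, blood, and immune disorders	1	E15-E34.9
other_endocrine	Other endocrine, nutritional, blood, and immune disorders	1	E65-E90.9
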
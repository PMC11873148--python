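drug,viability_A6,viability_G2,viability_H2,delta_G2,delta_H2,category
Ridaforolimus,91.48,91.26,70.93,-0.22,-20.55,sensitizer
Irinotecan,73.08,78.63,62.25,5.55,-10.83,sensitizer
Trichostatin A,82.60,82.77,66.50,0.18,-16.10,sensitizer
Rigosertib,32.73,20.71,12.10,-12.02,-20.63,sensitizer
PIK-93,91.37,99.58,80.72,8.21,-10.65,sensitizer
KRN 633,110.29,104.40,99.15,-5.89,-11.14,sensitizer
Degrasyn,108.16,101.21,94.55,-6.95,-13.61,sensitizer
KX2-391,31.75,21.10,16.91,-10.65,-14.84,sensitizer
Bosutinib,87.65,82.15,77.89,-5.50,-9.76,sensitizer
Vorinostat,85.33,68.27,87.93,-17.07,2.59,sensitizer
Ruxolitinib,94.34,78.24,93.11,-16.09,-1.23,sensitizer
TSU-68,97.68,91.06,79.00,-6.62,-18.67,sensitizer
MLN8054,79.47,68.91,86.04,-10.55,6.57,sensitizer
TAE684,80.06,56.97,69.66,-23.09,-10.40,sensitizer
BIX 02189,94.80,77.55,94.05,-17.25,-0.75,sensitizer
XL147 analogue,100.31,92.09,90.22,-8.22,-10.09,sensitizer
Ipatasertib,90.64,91.59,79.27,0.96,-11.37,sensitizer
CX-4945,91.08,82.62,78.29,-8.46,-12.80,sensitizer
A66,85.93,77.99,70.63,-7.94,-15.29,sensitizer
EPZ5676,90.97,92.13,73.83,1.17,-17.14,sensitizer
PF-00562271,79.52,69.93,70.15,-9.59,-9.37,sensitizer
Crenolanib,94.33,87.49,78.37,-6.85,-15.96,sensitizer
AZ 628,90.29,79.64,87.81,-10.65,-2.48,sensitizer
Regorafenib,95.87,86.84,95.32,-9.03,-0.55,sensitizer
BX-912,92.73,77.24,75.79,-15.49,-16.94,sensitizer
AZD7762,79.28,71.71,65.42,-7.57,-13.87,sensitizer
Cabozantinib,97.96,72.82,87.80,-25.14,-10.16,sensitizer
PD318088,70.13,56.91,65.82,-13.22,-4.32,sensitizer
GSK461364,37.66,19.70,17.36,-17.96,-20.30,sensitizer
Indirubin,89.53,83.37,76.67,-6.16,-12.86,sensitizer
Piceatannol,92.99,77.20,93.73,-15.79,0.74,sensitizer
GSK J4 HCl,92.75,72.53,91.59,-20.22,-1.16,sensitizer
Y-27632 2HCl,95.74,86.40,76.99,-9.34,-18.75,sensitizer
Brivanib,91.92,74.72,88.98,-17.20,-2.94,sensitizer
U0126-EtOH,86.16,85.01,66.65,-1.15,-19.51,sensitizer
Foretinib,86.76,78.96,73.34,-7.80,-13.42,sensitizer
R406,74.24,61.54,66.69,-12.69,-7.55,sensitizer
Everolimus,80.53,75.95,62.89,-4.58,-17.65,sensitizer
KU-60019,91.90,91.41,80.39,-0.50,-11.51,sensitizer
Alpelisib,88.12,74.41,77.06,-13.71,-11.06,sensitizer
SGC 0946,94.49,66.01,80.75,-28.47,-13.74,sensitizer
Flavopiridol,47.98,33.00,43.75,-14.98,-4.23,sensitizer
Resminostat,77.41,65.58,71.52,-11.83,-5.88,sensitizer
PKI-402,60.15,75.24,49.50,15.09,-10.65,sensitizer
Sunitinib Malate,87.87,83.56,70.80,-4.31,-17.07,sensitizer
TG100-115,90.52,61.59,83.66,-28.93,-6.86,sensitizer
ZSTK474,73.66,77.46,60.29,3.79,-13.37,sensitizer
HMN-214,50.59,35.61,46.45,-14.98,-4.14,sensitizer
ZM 447439,87.61,78.13,77.21,-9.47,-10.40,sensitizer
SGX-523,88.91,84.83,73.50,-4.08,-15.40,sensitizer
CP-673451,88.17,80.10,76.93,-8.06,-11.24,sensitizer
BS-181 HCl,95.44,81.65,89.67,-13.79,-5.77,sensitizer
Tyrphostin AG 879,97.34,83.36,85.16,-13.98,-12.18,sensitizer
WYE-125132,54.30,41.34,49.12,-12.96,-5.18,sensitizer
IWR-1-endo,92.47,74.50,70.23,-17.97,-22.25,sensitizer
Apitolisib,71.24,48.40,57.48,-22.84,-13.76,sensitizer
PD184352,78.82,62.21,68.40,-16.61,-10.42,sensitizer
Enzastaurin,73.46,52.14,57.49,-21.33,-15.97,sensitizer
GSK1059615,73.50,70.04,60.26,-3.46,-13.24,sensitizer
OSI-906,91.35,71.84,88.73,-19.51,-2.62,sensitizer
AEE788,91.62,82.55,81.98,-9.08,-9.65,sensitizer
GSK690693,98.38,86.89,94.21,-11.49,-4.18,sensitizer
Paclitaxel,20.26,9.36,11.09,-10.90,-9.18,sensitizer
WP1066,90.79,74.00,80.80,-16.79,-9.99,sensitizer
Volasertib,55.34,54.54,37.89,-0.80,-17.45,sensitizer
VX-702,93.15,84.03,97.17,-9.12,4.02,sensitizer
ICG-001,98.04,87.25,95.26,-10.79,-2.78,sensitizer
Tivantinib,72.10,49.25,72.04,-22.85,-0.06,sensitizer
BEZ235,70.67,60.35,54.63,-10.32,-16.04,sensitizer
Palomid 529,91.17,80.29,91.19,-10.88,0.02,sensitizer
PF-04691502,68.92,69.44,52.57,0.52,-16.34,sensitizer
Masitinib,96.91,106.49,100.28,9.58,3.37,protector
Pemetrexed,86.70,106.05,105.69,19.35,18.98,protector
NVP-BHG712,94.10,106.11,99.49,12.00,5.38,protector
TAK-733,70.86,79.99,80.41,9.13,9.55,protector
CHIR-124,78.60,83.76,89.55,5.16,10.95,protector
PD0325901,62.16,62.98,74.31,0.82,12.15,protector
Pictilisib,76.83,87.81,85.52,10.98,8.68,protector
Ponatinib,68.09,82.19,61.83,14.11,-6.25,protector
LDN-193189,81.48,93.38,82.53,11.90,1.05,protector
Tivozanib,84.76,88.41,94.54,3.64,9.78,protector
PI-103,50.54,74.06,78.62,23.52,28.08,protector
R788,79.61,90.35,81.33,10.73,1.72,protector
AZD5438,58.22,73.44,70.15,15.21,11.92,protector
WAY-600,73.37,78.66,83.75,5.28,10.38,protector
Rapamycin,59.06,81.16,67.46,22.10,8.40,protector
Pelitinib,50.54,68.77,60.12,18.23,9.58,protector
Pimasertib,58.26,51.09,68.23,-7.17,9.97,protector
SNS-032,96.01,106.59,106.96,10.58,10.95,protector
BMS-265246,66.23,88.81,70.08,22.57,3.85,protector
PP121,55.02,66.26,61.96,11.24,6.94,protector
Trametinib,54.56,53.74,64.22,-0.82,9.66,protector
Dovitinib,86.04,79.49,95.39,-6.55,9.35,protector
Sorafenib Tosylate,80.74,96.98,93.41,16.24,12.67,protector
Amuvatinib,82.89,76.30,95.38,-6.59,12.49,protector
OSI-027,57.49,58.22,68.54,0.72,11.04,protector
PKI-402,60.15,75.24,49.50,15.09,-10.65,protector
Roxadustat,95.80,104.86,96.12,9.06,0.33,protector
PLX-4720,91.75,105.83,97.75,14.08,6.00,protector
IMD 0354,80.03,90.21,83.51,10.18,3.47,protector
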
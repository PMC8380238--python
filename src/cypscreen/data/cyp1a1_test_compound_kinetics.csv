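compound,cas,ic50_display,ic50_uM,ic50_lo,ic50_hi,ki_uM,ki_lo,ki_hi,alpha,alpha_lo,alpha_hi,moi
Ketoconazole,65277-42-1,0.099,0.099,0.066,0.13,0.11,0.063,0.24,0.68,0.27,1.4,noncompetitive
Zearalenone,17924-92-4,0.7,0.7,0.49,0.91,0.66,0.43,1.1,3.5,1.5,8.3,mixed
Bisphenol A,80-05-7,2.4,2.4,2,2.8,0.53,0.36,0.85,9.1,3.8,40,competitive
Amiodarone,19774-82-4,7.8,7.8,4.3,11,1.4,0.85,2.7,4.7,1.7,15,competitive
Cyproterone acetate,427-51-0,9.9,9.9,1.5,18,8.8,5.7,15,7,2.8,28,competitive
Dibutyl phthalate,84-74-2,10,10,5.6,15,1.6,1.2,2.4,13,5.5,210,competitive
Tamoxifen,10540-29-1,12,12,7.2,16,3.6,2,8.2,7.2,2.2,44,competitive
Bicalutamide,90357-06-5,14,14,11,18,6.6,4.4,11,2.7,1.2,5.9,mixed
Diethyl phthalate,84-66-2,38,38,21,56,10,6.4,18,8.4,3.2,72,competitive
Propyl paraben,94-13-3,39,39,29,48,17,11,27,6.2,2.5,21,competitive
Progesterone,57-83-0,41,41,19,63,20,12,41,4.3,1.5,18,competitive
Estradiol,50-28-2,43,43,17,70,13,8.2,22,4.3,1.7,15,competitive
beta-Myrcene,123-35-3,52,52,42,62,11,7.3,17,3.5,1.6,7.6,mixed
DHEA,53-43-0,130,130,67,200,,,,,,,
Anastrozole,120511-73-1,190,190,19,370,,,,,,,
Estetrol,15183-37-6,> 200,,,,,,,,,,
"2,4'-DDT",789-02-6,> 200,,,,,,,,,,
Estrone,53-16-7,> 200,,,,,,,,,,
p-Phenylenediamine,106-50-3,> 200,,,,,,,,,,
Cyclophosphamide,6055-19-2,inf,,,,,,,,,,
Diacetyl,431-03-8,inf,,,,,,,,,,
Estriol,50-27-1,inf,,,,,,,,,,
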
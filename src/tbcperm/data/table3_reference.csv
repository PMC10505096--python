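# Experimental transwell apparent permeabilities (25-37C) with literature
# sources, plus two provenance-only columns: the 167C-calibration
# prediction (rounded line, m = 1.12, c = -4.82) and an Arrhenius
# extrapolation from earlier multi-temperature work.  The last column is
# the printed |log10 P_exp - log10 P_pred| between columns 2 and 4.
name,P_app_exp,reference,P_app_pred_167C,P_sim_37C_arrhenius,oom_error
Atenolol,1.30e-6,Adson (1995),1.01e-5,9.38e-6,0.89
Bupropion,4.75e-5,Summerfield (2007),2.48e-5,1.18e-6,0.28
Dilantin,2.70e-5,Summerfield (2007),4.97e-5,2.31e-5,0.26
Duloxetine,1.66e-5,Hellinger (2012),6.17e-6,4.86e-7,0.43
Effexor,6.00e-5,Hellinger (2012),3.23e-5,9.70e-6,0.27
Ethanol,1.10e-3,Brahm (1983),1.77e-4,1.58e-1,0.79
Ibuprofen,2.70e-5,in-house,3.44e-5,1.45e-6,0.10
Ketoprofen,8.00e-5,Sun (2002),1.38e-4,8.68e-5,0.24
Nadolol,3.30e-7,Yamashita (2000),9.31e-6,1.25e-5,1.45
Naproxen,3.90e-5,Pade (1998),1.12e-4,2.30e-5,0.46
Nicotine,1.78e-4,Garberg (2005),1.96e-4,2.16e-1,0.05
Propanol,3.30e-3,Brahm (1983),3.58e-4,3.06e-1,0.97
Ritalin,2.47e-5,Yang (2016),8.24e-5,2.69e-3,0.52
Caffeine,2.10e-5,in-house,1.01e-6,3.27e-2,1.32
Doxorubicin,1.00e-7,Hellinger (2012),8.01e-7,4.68e-2,0.90
Ethosuximide,9.00e-6,Summerfield (2007),1.03e-5,2.40e-1,0.06
Glycerol,9.50e-6,Shah (1989),1.44e-6,2.00e-2,0.82
Temozolomide,1.86e-6,Avdeef (2012),1.56e-6,3.12e-2,0.08
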
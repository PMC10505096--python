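# Worked prediction examples for the two calibration lines, as printed.
# train_167C rows use the full-precision 167C line (m = 1.124, c = -4.819)
# on the listed P_sim inputs; train_127C rows use the 127C line
# (m = 1.17, c = -3.73).  validation rows come from simulations whose
# P_sim inputs are not available here, so their predictions are fixture
# values only.  Note the nicotine experimental value in this table
# (1.73e-4) is a variant of the reference-table value (1.78e-4); both are
# kept, with this file's value used when reproducing these rows.
section,name,p_sim_input,p_app_exp,p_app_pred,oom_error_printed
validation,Sertraline,,2.10e-6,1.67e-6,1.25000
validation,Risperdal,,3.00e-5,5.24e-5,0.24000
validation,Diazepam,,4.60e-5,5.27e-5,0.94000
validation,Lacosamide,,1.60e-5,1.02e-4,0.81000
train_167C,Ethanol,8.99e0,1.10e-3,1.79e-4,0.78837
train_167C,Nicotine,9.85e0,1.73e-4,1.98e-4,0.05958
train_167C,Bupropion,1.56e0,4.75e-5,2.50e-5,0.27862
train_167C,Dilantin,2.89e0,2.70e-5,5.00e-5,0.26769
train_167C,Caffeine,9.00e-2,2.10e-5,1.01e-6,1.31665
train_167C,Glycerol,1.20e-1,9.50e-6,1.40e-6,0.83172
train_167C,Temozolomide,1.30e-1,1.86e-6,1.53e-6,0.08444
train_167C,Atenolol,7.00e-1,1.30e-6,1.02e-5,0.89295
train_167C,Doxorubicin,7.00e-2,1.00e-7,7.64e-7,0.88289
train_127C,Propanol,3.73e0,3.30e-3,8.69e-4,0.57961
train_127C,Ethanol,3.08e0,1.10e-3,6.94e-4,0.20028
train_127C,Nicotine,2.51e0,1.73e-4,5.47e-4,0.49977
train_127C,Ketoprofen,2.11e-1,8.00e-5,3.02e-5,0.42368
train_127C,Bupropion,7.40e-2,4.75e-5,8.85e-6,0.72969
train_127C,Dilantin,1.83e-1,2.70e-5,2.55e-5,0.02430
train_127C,Duloxetine,5.72e-2,1.66e-5,6.55e-6,0.40395
train_127C,Atenolol,7.73e-2,1.30e-6,9.31e-6,0.85523
train_127C,Nadolol,1.20e-1,1.00e-7,1.56e-5,2.19264
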
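label	x	y	z
Cz	0.00000000	0.00000000	1.00000000
AFz	0.00000000	0.80901699	0.58778525
Fz	0.00000000	0.58778525	0.80901699
FCz	0.00000000	0.30901699	0.95105652
CPz	-0.00000000	-0.30901699	0.95105652
Pz	-0.00000000	-0.58778525	0.80901699
POz	-0.00000000	-0.80901699	0.58778525
Fpz	0.00000000	0.95105652	0.30901699
Fp1	-0.29389263	0.90450850	0.30901699
AF7	-0.55901699	0.76942088	0.30901699
F7	-0.76942088	0.55901699	0.30901699
FT7	-0.90450850	0.29389263	0.30901699
T7	-0.95105652	0.00000000	0.30901699
TP7	-0.90450850	-0.29389263	0.30901699
P7	-0.76942088	-0.55901699	0.30901699
PO7	-0.55901699	-0.76942088	0.30901699
O1	-0.29389263	-0.90450850	0.30901699
Oz	-0.00000000	-0.95105652	0.30901699
O2	0.29389263	-0.90450850	0.30901699
PO8	0.55901699	-0.76942088	0.30901699
P8	0.76942088	-0.55901699	0.30901699
TP8	0.90450850	-0.29389263	0.30901699
T8	0.95105652	0.00000000	0.30901699
FT8	0.90450850	0.29389263	0.30901699
F8	0.76942088	0.55901699	0.30901699
AF8	0.55901699	0.76942088	0.30901699
Fp2	0.29389263	0.90450850	0.30901699
AFF7h	-0.67249851	0.67249851	0.30901699
FFT7h	-0.84739756	0.43177062	0.30901699
FTT7h	-0.93934743	0.14877802	0.30901699
TTP7h	-0.93934743	-0.14877802	0.30901699
TPP7h	-0.84739756	-0.43177062	0.30901699
PPO7h	-0.67249851	-0.67249851	0.30901699
POO9h	-0.43177062	-0.84739756	0.30901699
AFF8h	0.67249851	0.67249851	0.30901699
FFT8h	0.84739756	0.43177062	0.30901699
FTT8h	0.93934743	0.14877802	0.30901699
TTP8h	0.93934743	-0.14877802	0.30901699
TPP8h	0.84739756	-0.43177062	0.30901699
PPO8h	0.67249851	-0.67249851	0.30901699
POO10h	0.43177062	-0.84739756	0.30901699
F9	-0.80901699	0.58778525	0.00000000
FT9	-0.95105652	0.30901699	0.00000000
FTT9h	-0.98768834	0.15643447	0.00000000
TP9	-0.95105652	-0.30901699	0.00000000
TPP9h	-0.89100652	-0.45399050	0.00000000
P9	-0.80901699	-0.58778525	0.00000000
PO9	-0.58778525	-0.80901699	0.00000000
I1	-0.30901699	-0.95105652	0.00000000
Iz	-0.00000000	-1.00000000	0.00000000
I2	0.30901699	-0.95105652	0.00000000
PO10	0.58778525	-0.80901699	0.00000000
P10	0.80901699	-0.58778525	0.00000000
TPP10h	0.89100652	-0.45399050	0.00000000
TP10	0.95105652	-0.30901699	0.00000000
FTT10h	0.98768834	0.15643447	0.00000000
FT10	0.95105652	0.30901699	0.00000000
F10	0.80901699	0.58778525	0.00000000
AF3	-0.29429202	0.83096162	0.47211756
AF4	0.29429202	0.83096162	0.47211756
AFF1	-0.18642810	0.74326257	0.64249927
AFF2	0.18642810	0.74326257	0.64249927
AFF5h	-0.44973570	0.74129535	0.49821583
AFF6h	0.44973570	0.74129535	0.49821583
F1	-0.22281840	0.63455568	0.74006152
F2	0.22281840	0.63455568	0.74006152
F3	-0.43302743	0.64541636	0.62922569
F4	0.43302743	0.64541636	0.62922569
F5	-0.61873127	0.61975270	0.48278174
F6	0.61873127	0.61975270	0.48278174
FFC1h	-0.12931472	0.48309366	0.86596664
FFC2h	0.12931472	0.48309366	0.86596664
FFC3h	-0.37857478	0.51455883	0.76935710
FFC4h	0.37857478	0.51455883	0.76935710
FFC5h	-0.60040558	0.50874214	0.61700452
FFC6h	0.60040558	0.50874214	0.61700452
FC1	-0.28394295	0.35069925	0.89240486
FC2	0.28394295	0.35069925	0.89240486
FC3	-0.54352330	0.36229116	0.75718395
FC4	0.54352330	0.36229116	0.75718395
FC5	-0.75646880	0.34279811	0.55699588
FC6	0.75646880	0.34279811	0.55699588
FCC1h	-0.15305692	0.17043974	0.97340838
FCC2h	0.15305692	0.17043974	0.97340838
FCC3h	-0.44467040	0.18603042	0.87616261
FCC4h	0.44467040	0.18603042	0.87616261
FCC5h	-0.69415660	0.18399690	0.69591073
FCC6h	0.69415660	0.18399690	0.69591073
C1	-0.30901699	0.00000000	0.95105652
C2	0.30901699	0.00000000	0.95105652
C3	-0.58778525	0.00000000	0.80901699
C4	0.58778525	0.00000000	0.80901699
C5	-0.80901699	0.00000000	0.58778525
C6	0.80901699	0.00000000	0.58778525
CCP1h	-0.15305692	-0.17043974	0.97340838
CCP2h	0.15305692	-0.17043974	0.97340838
CCP3h	-0.44467040	-0.18603042	0.87616261
CCP4h	0.44467040	-0.18603042	0.87616261
CCP5h	-0.69415660	-0.18399690	0.69591073
CCP6h	0.69415660	-0.18399690	0.69591073
CP1	-0.28394295	-0.35069925	0.89240486
CP2	0.28394295	-0.35069925	0.89240486
CP3	-0.54352330	-0.36229116	0.75718395
CP4	0.54352330	-0.36229116	0.75718395
CP5	-0.75646880	-0.34279811	0.55699588
CP6	0.75646880	-0.34279811	0.55699588
CPP1h	-0.12931472	-0.48309366	0.86596664
CPP2h	0.12931472	-0.48309366	0.86596664
CPP3h	-0.37857478	-0.51455883	0.76935710
CPP4h	0.37857478	-0.51455883	0.76935710
CPP5h	-0.60040558	-0.50874214	0.61700452
CPP6h	0.60040558	-0.50874214	0.61700452
P1	-0.22281840	-0.63455568	0.74006152
P2	0.22281840	-0.63455568	0.74006152
P3	-0.43302743	-0.64541636	0.62922569
P4	0.43302743	-0.64541636	0.62922569
P5	-0.61873127	-0.61975270	0.48278174
P6	0.61873127	-0.61975270	0.48278174
PPO1h	-0.09368645	-0.72885982	0.67822284
PPO2h	0.09368645	-0.72885982	0.67822284
PPO5h	-0.44973570	-0.74129535	0.49821583
PPO6h	0.44973570	-0.74129535	0.49821583
PO3	-0.29429202	-0.83096162	0.47211756
PO4	0.29429202	-0.83096162	0.47211756
AFp1	-0.07473488	0.90360592	0.42179501
AFp2	0.07473488	0.90360592	0.42179501
POO1	-0.11162580	-0.89791678	0.42577592
POO2	0.11162580	-0.89791678	0.42577592
nasion	0.00000000	1.00000000	0.00000000
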
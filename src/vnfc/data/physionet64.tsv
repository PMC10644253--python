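label	x	y
Fc5	-0.787211	0.190070
Fc3	-0.511345	0.193012
Fc1	-0.248875	0.190051
Fcz	0.002619	0.190734
Fc2	0.256568	0.195006
Fc4	0.520768	0.198322
Fc6	0.791122	0.198299
C5	-0.769909	-0.131959
C3	-0.501982	-0.089337
C1	-0.242932	-0.067078
Cz	0.002539	-0.058055
C2	0.255559	-0.065288
C4	0.514622	-0.083577
C6	0.778891	-0.119241
Cp5	-0.685245	-0.400776
Cp3	-0.449359	-0.332365
Cp1	-0.219706	-0.292577
Cpz	0.002305	-0.282765
Cp2	0.237405	-0.291148
Cp4	0.465241	-0.325731
Cp6	0.698594	-0.386527
Fp1	-0.347538	0.990749
Fpz	0.001288	1.012355
Fp2	0.348510	0.990453
Af7	-0.672295	0.840646
Af3	-0.338301	0.771320
Afz	0.002110	0.736922
Af4	0.350722	0.763327
Af8	0.672538	0.840404
F7	-0.931084	0.562845
F5	-0.695972	0.518588
F3	-0.458234	0.484385
F1	-0.223905	0.463604
Fz	0.002452	0.459555
F2	0.240105	0.468606
F4	0.471587	0.494045
F6	0.707753	0.519289
F8	0.930257	0.565743
Ft7	-1.069702	0.186995
Ft8	1.067324	0.201119
T7	-1.050320	-0.199911
T8	1.053360	-0.185964
T9	-1.299611	-0.239494
T10	1.298608	-0.248328
Tp7	-0.919818	-0.499016
Tp8	0.923965	-0.491910
P7	-0.712928	-0.722951
P5	-0.546810	-0.620114
P3	-0.369026	-0.548505
P1	-0.180714	-0.508450
Pz	0.001978	-0.494166
P2	0.198492	-0.500506
P4	0.382663	-0.540037
P6	0.552419	-0.617652
P8	0.718109	-0.718233
Po7	-0.482347	-0.857804
Po3	-0.268118	-0.740604
Poz	0.001492	-0.707234
Po4	0.271335	-0.743956
Po8	0.487680	-0.855268
O1	-0.240830	-0.920705
Oz	0.000861	-0.919221
O2	0.244746	-0.919817
Iz	0.000043	-1.122384
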
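{
 "Fc5": 7,
 "Fc3": 7,
 "Fc1": 7,
 "Fcz": 6,
 "Fc2": 5,
 "Fc4": 5,
 "Fc6": 4,
 "C5": 0,
 "C3": 0,
 "C1": 0,
 "Cz": 2,
 "C2": 4,
 "C4": 4,
 "C6": 4,
 "Cp5": 0,
 "Cp3": 0,
 "Cp1": 1,
 "Cpz": 2,
 "Cp2": 3,
 "Cp4": 3,
 "Cp6": 3,
 "Fp1": 6,
 "Fpz": 6,
 "Fp2": 6,
 "Af7": 7,
 "Af3": 6,
 "Afz": 6,
 "Af4": 5,
 "Af8": 5,
 "F7": 7,
 "F5": 7,
 "F3": 7,
 "F1": 6,
 "Fz": 6,
 "F2": 5,
 "F4": 5,
 "F6": 5,
 "F8": 5,
 "Ft7": 7,
 "Ft8": 4,
 "T7": 0,
 "T8": 4,
 "T9": 0,
 "T10": 4,
 "Tp7": 0,
 "Tp8": 4,
 "P7": 1,
 "P5": 1,
 "P3": 1,
 "P1": 1,
 "Pz": 2,
 "P2": 3,
 "P4": 3,
 "P6": 3,
 "P8": 3,
 "Po7": 1,
 "Po3": 1,
 "Poz": 2,
 "Po4": 2,
 "Po8": 3,
 "O1": 1,
 "Oz": 2,
 "O2": 2,
 "Iz": 2
}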
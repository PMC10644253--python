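{
 "56": [
  "Af3",
  "Af4",
  "Af7",
  "Af8",
  "Afz",
  "C1",
  "C2",
  "C3",
  "C4",
  "C5",
  "C6",
  "Cp1",
  "Cp2",
  "Cp3",
  "Cp4",
  "Cp5",
  "Cp6",
  "Cpz",
  "Cz",
  "F1",
  "F2",
  "F3",
  "F4",
  "F5",
  "F6",
  "F7",
  "F8",
  "Fc1",
  "Fc2",
  "Fc3",
  "Fc4",
  "Fc5",
  "Fc6",
  "Fcz",
  "Fp1",
  "Fp2",
  "Fpz",
  "Ft7",
  "Ft8",
  "Fz",
  "Iz",
  "O1",
  "O2",
  "P1",
  "P2",
  "P6",
  "P7",
  "Po7",
  "Po8",
  "Poz",
  "T10",
  "T7",
  "T8",
  "T9",
  "Tp7",
  "Tp8"
 ],
 "48": [
  "Af7",
  "Af8",
  "Afz",
  "C1",
  "C2",
  "C3",
  "C4",
  "C5",
  "C6",
  "Cp3",
  "Cp4",
  "Cp5",
  "Cp6",
  "Cz",
  "F1",
  "F2",
  "F3",
  "F5",
  "F7",
  "F8",
  "Fc1",
  "Fc2",
  "Fc3",
  "Fc4",
  "Fc5",
  "Fc6",
  "Fcz",
  "Fp1",
  "Fp2",
  "Fpz",
  "Ft7",
  "Ft8",
  "Iz",
  "O1",
  "O2",
  "P1",
  "P2",
  "P6",
  "P7",
  "Po7",
  "Po8",
  "Poz",
  "T10",
  "T7",
  "T8",
  "T9",
  "Tp7",
  "Tp8"
 ],
 "40": [
  "Af7",
  "Af8",
  "Afz",
  "C2",
  "C3",
  "C4",
  "C5",
  "C6",
  "Cp5",
  "Cz",
  "F1",
  "F2",
  "F7",
  "F8",
  "Fc1",
  "Fc2",
  "Fc3",
  "Fc4",
  "Fc5",
  "Fc6",
  "Fp1",
  "Fp2",
  "Fpz",
  "Ft7",
  "Ft8",
  "Iz",
  "O1",
  "O2",
  "P1",
  "P2",
  "P6",
  "P7",
  "Po7",
  "Poz",
  "T10",
  "T7",
  "T8",
  "T9",
  "Tp7",
  "Tp8"
 ],
 "32": [
  "Af7",
  "Af8",
  "Afz",
  "C3",
  "C4",
  "C5",
  "Cp5",
  "Cz",
  "F1",
  "F2",
  "F7",
  "F8",
  "Fc2",
  "Fc3",
  "Fc5",
  "Fc6",
  "Fp1",
  "Fp2",
  "Fpz",
  "Ft7",
  "Ft8",
  "Iz",
  "O1",
  "O2",
  "P1",
  "P2",
  "P6",
  "P7",
  "Poz",
  "T10",
  "T9",
  "Tp8"
 ],
 "24": [
  "Af7",
  "Af8",
  "C3",
  "C4",
  "Cp5",
  "Cz",
  "F1",
  "F2",
  "F7",
  "F8",
  "Fc5",
  "Fc6",
  "Fp1",
  "Fp2",
  "Fpz",
  "Iz",
  "O2",
  "P1",
  "P2",
  "P6",
  "P7",
  "T10",
  "T9",
  "Tp8"
 ],
 "16": [
  "Af7",
  "Af8",
  "C3",
  "C4",
  "Cz",
  "F1",
  "F2",
  "Fc5",
  "Fc6",
  "Fpz",
  "Iz",
  "P1",
  "P6",
  "P7",
  "T10",
  "T9"
 ]
}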
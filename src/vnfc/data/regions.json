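{
 "frontal": [
  "Fc5",
  "Fc3",
  "Fc1",
  "Fcz",
  "Fc2",
  "Fc4",
  "Fc6",
  "Fp1",
  "Fpz",
  "Fp2",
  "Af7",
  "Af3",
  "Afz",
  "Af4",
  "Af8",
  "F7",
  "F5",
  "F3",
  "F1",
  "Fz",
  "F2",
  "F4",
  "F6",
  "F8",
  "Ft7",
  "Ft8"
 ],
 "central": [
  "Fc5",
  "Fc3",
  "Fc1",
  "Fcz",
  "Fc2",
  "Fc4",
  "Fc6",
  "C5",
  "C3",
  "C1",
  "Cz",
  "C2",
  "C4",
  "C6",
  "Cp5",
  "Cp3",
  "Cp1",
  "Cpz",
  "Cp2",
  "Cp4",
  "Cp6"
 ],
 "parietal": [
  "Cp5",
  "Cp3",
  "Cp1",
  "Cpz",
  "Cp2",
  "Cp4",
  "Cp6",
  "Tp7",
  "Tp8",
  "P7",
  "P5",
  "P3",
  "P1",
  "Pz",
  "P2",
  "P4",
  "P6",
  "P8",
  "Po7",
  "Po3",
  "Poz",
  "Po4",
  "Po8"
 ],
 "occipital": [
  "Po7",
  "Po3",
  "Poz",
  "Po4",
  "Po8",
  "O1",
  "Oz",
  "O2",
  "Iz"
 ],
 "temporal": [
  "Ft7",
  "Ft8",
  "T7",
  "T8",
  "T9",
  "T10",
  "Tp7",
  "Tp8"
 ]
}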
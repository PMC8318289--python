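{
 "description": "Full-precision settled resting state, generated by scripts/calibrate.py (relaxation with zero water permeability from the published post-calibrated values).",
 "t_relax_s": 500.0,
 "phi_mn0": [
  -0.06703904711079095,
  -0.06703553575953242
 ],
 "phi_mg0": [
  -0.08356829113690056,
  -0.08356134505964538
 ],
 "concentrations": {
  "Na": {
   "sn": 18.772577278162963,
   "se": 142.22492633336233,
   "sg": 14.472209303890361,
   "dn": 18.781505986477026,
   "de": 142.1840473699755,
   "dg": 14.46922057979147
  },
  "K": {
   "sn": 138.0384085969239,
   "se": 3.5190095998348814,
   "sg": 101.2514714788043,
   "dn": 138.0296954522111,
   "de": 3.532171995205949,
   "dg": 101.25483367454932
  },
  "Cl": {
   "sn": 7.111004410023011,
   "se": 131.84353434727333,
   "sg": 5.72363656816803,
   "dn": 7.111296461890988,
   "de": 131.81657254467416,
   "dg": 5.724009113949479
  },
  "Ca": {
   "sn": 0.01000000045283891,
   "se": 1.099773526513507,
   "sg": 0.0,
   "dn": 0.010038478605754428,
   "de": 1.1001495153711152,
   "dg": 0.0
  }
 },
 "gating": {
  "h": 0.9993258965192167,
  "n": 0.0002999707340964117,
  "s": 0.007593309204986457,
  "c": 0.00560027605330633,
  "q": 0.01156051425752398,
  "z": 1.0
 },
 "kir_baseline": {
  "K_e_basal": 3.5,
  "E_K_basal": -0.08962460681287736
 }
}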
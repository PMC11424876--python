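# Drug-specific model inputs for NH130, a selective 5-HT2A inverse agonist.
# Molecular weight, LogP, pKa, solubility and Papp are compound metadata
# (plausibility of the perfusion-limited treatment); the Kp map and
# blood:plasma ratio enter the dynamics.

[drug]
name = "NH130"
molecular_weight = 423.52      # g/mol
logp = 4.1
pka = [1.949, 5.2, 6.1]
solubility_mg_ml = 5.87
papp_cm_s = 0.8e-6
# blood:plasma ratio is not reported for this compound; unity assumed, with
# the unbound fraction absorbed into the calibrated lumped hepatic clearance
blood_to_plasma = 1.0

[drug.kp]                      # tissue-to-plasma partition coefficients
lung = 0.51
adipose = 19.88
muscle = 1.75
liver = 2.85
spleen = 1.78
heart = 1.20
brain = 4.50
kidney = 1.78
skin = 2.29
reproductive = 1.79
red_marrow = 5.00
yellow_marrow = 19.88
rest_of_body = 1.80
# no explicit gastrointestinal Kp is reported; the rest-of-body value is reused
gut = 1.80

[absorption]
ka = 0.06        # 1/h, starting value; replaced by calibration
f_abs = 1.0      # first-pass assigned entirely to the liver
tlag = 0.0       # h

[elimination]
cl_hepatic = 260.0   # L/h, starting value; replaced by calibration

[calibration]
# 60 mg reference-group predicted values the model is benchmarked against
reference_dose_mg = 60.0
target_cmax_ng_ml = 12.26
target_auc_0inf_h_ng_ml = 228.63
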
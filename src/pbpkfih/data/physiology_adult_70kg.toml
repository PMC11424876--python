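# Reference 70-kg adult physiology: tissue volumes (L) and blood flows (L/h)
# from standard compiled reference-human tables. flows.liver is the
# hepatic-artery flow; gut and spleen outflow drains to the liver (portal
# inflow). rest_of_body closes the flow balance so systemic flows sum exactly
# to cardiac output. Calibration targets make downstream predictions robust
# to reasonable edits of this table.

body_weight_kg = 70.0
cardiac_output_l_h = 390.0
arterial_volume_l = 1.73
venous_volume_l = 3.88

[volumes_l]
lung = 0.53
adipose = 14.5
muscle = 29.0
liver = 1.69
gut = 1.10
spleen = 0.19
heart = 0.33
brain = 1.45
kidney = 0.31
skin = 3.41
reproductive = 0.05
red_marrow = 1.17
yellow_marrow = 2.37
rest_of_body = 2.00

[flows_l_h]
adipose = 19.5
muscle = 66.3
liver = 23.4
gut = 62.4
spleen = 7.8
heart = 15.6
brain = 46.8
kidney = 74.1
skin = 19.5
reproductive = 1.2
red_marrow = 11.7
yellow_marrow = 3.9
rest_of_body = 37.8
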
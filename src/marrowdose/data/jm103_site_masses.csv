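site,body_tissue_g,rbm_g,cortical_g,trabecular_g,soft_g,blood_g
cranium,1346,91,774,308,264,28
mandible,165,9,80,52,33,3
cervical_vertebra,207,45,134,12,61,8
thoracic_vertebra,654,187,315,77,262,32
lumbar_vertebra,590,143,222,118,249,30
sacrum,261,115,128,12,120,14
clavicles,111,10,52,28,32,3
scapulae,310,34,143,70,97,8
sternum,107,36,39,21,47,6
ribs,945,187,325,226,394,48
os_coxae,1057,221,388,258,412,38
humeri,589,29,282,122,193,10
forearm,361,0,205,55,100,3
wrist_hand,220,0,115,36,69,2
femora,1653,84,665,440,547,24
tibiae_fibulae_patellae,1563,0,669,367,527,16
ankle_foot,872,0,299,262,313,9
os_hyoideum,4,0,2,1,1,0
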
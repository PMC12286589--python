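# Schematic radon-like inhalation system. SYNTHETIC rates: plausible in
# ordering (fast alveolar exchange, fat partitioning, exhalation dominant)
# but placeholders, not a reference biokinetic model.
from,to,rate_per_day
lung,blood,100.0
lung,excreta,900.0
blood,fat,70.0
fat,blood,7.0
blood,soft_tissue,30.0
soft_tissue,blood,30.0
blood,excreta,150.0
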
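# Default cohort profile: n=117 severe-TBI subjects, two latent cortisol
# trajectory classes (44/117 high), ~26 expected deaths by day 180,
# genotype carrier frequencies 0.581 (Val/Val) and 0.521 (T/T),
# mean weekly cortisol 24.28 ng/mL, mean weekly BDNF 0.19 ng/mL.
profile: paper_calibrated
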
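# Variant of the default profile whose marginal total-effect hazard ratio for
# BDNF is ~1.94, implying a true proportion mediated of ~30% on the
# log-hazard scale (used by the mediation-recovery studies).
profile: mediated30
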
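# Attitude of 30 first-born children (aged 3-5) toward a soon-to-be-born
# sibling, median-split on age and on sibling acceptance, so both margins
# are fixed at 15 (hypergeometric design).
# Source: Kramer & Gottman (1992), as tabulated in Anderson (2002), p. 14-15.
,lower_acceptance,higher_acceptance
younger,9,6
older,6,9
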
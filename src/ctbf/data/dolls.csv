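# Doll-color preference among 160 Nebraska school children aged 4-8.
# Source: Hraba & Grant (1970), J. Pers. Soc. Psychol. 16(3).
# Rows are the fixed sample sizes per race (independent multinomial design):
# 62 of 89 African American children preferred the black doll; 60 of 71
# white children preferred the white doll.
,black_doll,white_doll
african_american,62,27
white,11,60
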
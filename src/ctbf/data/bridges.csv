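# Phone calls to a female interviewer after a questionnaire conducted on a
# fear-arousing suspension bridge vs. a solid wood bridge.
# Source: Dutton & Aron (1974), J. Pers. Soc. Psychol. 30(4), Experiment 2.
# Rows are the fixed experimental groups (independent multinomial design).
,call,no_call
suspension_bridge,9,9
solid_bridge,2,14
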
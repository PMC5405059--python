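# Professional occupations of 775 fathers (rows) and their sons
# (columns); data collected by Emily Perrin and published by
# Pearson (1904), Drapers' Company Research Memoirs I, p. 33.
# Transcription validated against the grand total (775) and the
# Pearson chi-square statistic (1005.45, df=169) for this table.
,army,art,teacher_clerk_civil_servant,crafts,divinity,agriculture,landownership,law,literature,commerce,medicine,navy,politics_and_court,scholarship_and_science
army,28,0,4,0,0,0,1,3,3,0,3,1,5,2
art,2,51,1,1,2,0,0,1,2,0,0,0,1,1
teacher_clerk_civil_servant,6,5,7,0,9,1,3,6,4,2,1,1,2,7
crafts,0,12,0,6,5,0,0,1,7,1,2,0,0,10
divinity,5,5,2,1,54,0,0,6,9,4,12,3,1,13
agriculture,0,2,3,0,3,0,0,1,4,1,4,2,1,5
landownership,17,1,4,0,14,0,6,11,4,1,3,3,17,7
law,3,5,6,0,6,0,2,18,13,1,1,1,8,5
literature,0,1,1,0,4,0,0,1,4,0,2,1,1,4
commerce,12,16,4,1,15,0,0,5,13,11,6,1,7,15
medicine,0,4,2,0,1,0,0,0,3,0,20,0,5,6
navy,1,3,1,0,0,0,1,0,1,1,1,6,2,1
politics_and_court,5,0,2,0,3,0,1,8,1,2,2,3,23,1
scholarship_and_science,5,3,0,2,6,0,1,3,1,0,0,1,1,9
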
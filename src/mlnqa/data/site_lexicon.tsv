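phrase	category_id
station 1r	1R
station 1l	1L
station 2r	2R
2r	2R
right upper paratracheal	2R
station 2l	2L
2l	2L
left upper paratracheal	2L
station 3a	3A
prevascular	3A
station 3p	3P
retrotracheal	3P
station 4r	4R
4r	4R
right lower paratracheal	4R
station 4l	4L
4l	4L
left lower paratracheal	4L
station 5	5
aortopulmonary window	5
station 6	6
para-aortic	6
station 7	7
subcarinal	7
subcarinal lymph node	7
station 8	8
paraesophageal	8
station 9	9
pulmonary ligament	9
station 10r	10R
10r	10R
right hilar	10R
station 10l	10L
10l	10L
left hilar	10L
station 11r	11R
11r	11R
right interlobar	11R
station 11l	11L
11l	11L
left interlobar	11L
station 12r	12R
12r	12R
station 12l	12L
12l	12L
station 13r	13R
station 13l	13L
station 14r	14R
station 14l	14L
station 12	12
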
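network	label	x	y	z
ERN1	L superior frontal gyrus	-18	24	52
ERN1	L middle frontal gyrus	-42	22	38
ERN1	R middle frontal gyrus	44	24	36
ERN1	L inferior parietal lobule	-46	-48	46
ERN1	R inferior parietal lobule	48	-46	44
ERN1	R insula	36	20	-2
ERN1	cingulate gyrus	2	18	42
ERN1	precuneus	-6	-62	44
ERN1	R superior frontal gyrus	20	10	58
ERN2	L inferior frontal gyrus	-48	26	-2
ERN2	R inferior frontal gyrus	50	28	0
ERN2	L superior frontal gyrus medial	-10	52	30
ERN2	L superior temporal gyrus	-54	-8	-6
ERN2	L middle frontal gyrus	-38	48	10
ERN2	L middle temporal gyrus	-56	-38	-4
ERN2	L caudate	-10	10	4
ERN2	R tuber	34	-64	-30
ERN2	L inferior frontal gyrus orbital	-40	30	-14
ERN3	L amygdala	-22	-4	-18
ERN3	R amygdala	24	-2	-18
ERN3	L fusiform gyrus	-38	-52	-18
ERN3	R fusiform gyrus	40	-50	-18
ERN3	medial prefrontal gyrus	0	48	-10
ERN3	R thalamus	8	-20	6
ERN3	L parahippocampal gyrus	-26	-34	-14
ERN3	L inferior occipital gyrus	-40	-80	-10
ERN3	ventromedial prefrontal cortex	-2	40	-16
ERN4	L postcentral gyrus	-44	-26	50
ERN4	R postcentral gyrus	46	-24	48
ERN4	L insula	-38	-6	8
ERN4	L superior parietal lobule	-28	-54	60
ERN4	L cuneus	-8	-82	28
ERN4	L middle occipital gyrus	-32	-84	12
ERN4	R thalamus	12	-18	8
ERN4	R precuneus	10	-58	38
ERN4	R posterior cingulate	6	-42	24
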
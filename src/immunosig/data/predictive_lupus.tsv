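sequence	ratio_study1	ratio_study2	in_behavior_predictive	in_behavior_diagnostic	in_diagnostic
DKFHYWMYMLYGINDKIGSC	2.12	2.34			
DKLWKQIWTERHFMSHKGSC	1.57	4.3	x		
DWDSRQINPHIIHHVGRGSC	1.41	2.78			
EEHAHNKLFWWHRSRALGSC	1.61	2.52			
EMSWPRKPWRSKYYHEIGSC	1.46	3.36	x		x
ENILPTGRDRVAGWYRYGSC	1.51	3.1			x
FNRDHREFFEHFGFDEPGSC	1.4	3.61			x
GYNYWIVEWDQDQWLMNGSC	1.39	2.76			
HWKRRHKHKWPKRHPHKGSC	1.92	2.64			
KIWAMRKPRYQYWNQPAGSC	1.41	2.86			x
KWDHGQNGLFPPMHYIPGSC	1.54	3.07			
LEAHYKRSMHAQNWWEAGSC	1.41	2.6			
QYLWWQMLKIEWNSTYAGSC	6.22	2.61			
RHWYQDGSPLLAPVYKVGSC	1.48	3.07			
SYQRENESDEEEKNNEDGSC	1.64	2.38			
VEDNYGVTLRQPKYMGWGSC	1.41	2.36			
WNAMGKWKAMVDKTGDFGSC	2.1	2.4			
WNIHERHRFDQPYDYGHGSC	1.49	2.85			
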
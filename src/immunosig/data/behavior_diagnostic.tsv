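sequence	ratio_study1	ratio_study2	in_predictive	in_diagnostic	in_behavior_predictive
AGAFRERRYKPMMWLHVGSC	2.36	3.24			
AGVRHKFHPYLMQFRRHGSC	2.48	2.44			
AQLGMYGVYRPVEIWPDGSC	3.25	2.58		x	x
DDTLYNAHKHLKWFGFIGSC	2.71	3.21		x	
EKFKRPRWPHLPFTHWDGSC	2.66	2.46			
EPKLWFKPRRGGYRHRHGSC	2.87	3.02		x	
EPSLQVITEYNINFLTIGSC	2.4	3.03			x
EQEDYDDDEEQEQDEDDGSC	2.37	2.36			
ERNRRESDSKERKNYDHGSC	3.25	2.65			
FPGDRRSGRAFPEVRWRGSC	3.27	2.76		x	
GFHGPGMLGKTGRLSYGGSC	2.72	2.49			
GLVSRIPSVPKHDEWTFGSC	2.45	2.49		x	
GRVPQDFNTPSFDRVFWGSC	2.72	2.89		x	
GWLKAMGPFPWGRLVQNGSC	2.93	3.1		x	x
IGQRLKGKDENIRFENFGSC	2.4	4.23		x	x
ILDRRETAWNEHFSKFRGSC	3.37	3.22		x	
IPDGWLKNVYRVRVPWPGSC	2.64	2.34			
IRFVAILVFVIIILIARGSC	2.34	2.95			
KLLMTDFMAKWPRNGWYGSC	3.78	2.72		x	
KTHHSMWKGRITHELFAGSC	2.45	2.52			x
KVDYVNQWARRRIFMAPGSC	3.27	3.35		x	
LAFAWKPDPWQSLVTKFGSC	3.49	2.72			
PMLFWKWHRQLNQQGRRGSC	3.13	2.44		x	
PSAWEWIPRNQHLNKFRGSC	3.38	2.76		x	x
PYRFDWAALPLKKPMWRGSC	2.57	3.16		x	
QKKPPDYRTWHHPFYNGGSC	3.04	3.01		x	
QKRWLQLPRNLMWRRETGSC	2.92	2.77		x	
QRVPIVKWLLWEPRALPGSC	2.99	2.48			
QSAYHNHRMKWRKIGIEGSC	2.47	3.21			
QSHWFYDRTKDVYPGRHGSC	4.79	2.64		x	
RAAMHESLKNWRVYREWGSC	2.49	2.91		x	x
SRQGLHYNLDGLKPIFPGSC	2.77	3.34		x	
SSELDFRKYSFYVHRPDGSC	2.74	2.54			
TLNKRRSWRDGFTADEYGSC	2.31	2.39			
VDARMETFYDMQYPYYLGSC	2.37	2.46			
WKPIWHSFHKRRPQILNGSC	3.05	2.71		x	
WRTKAAMKWQKYQREHRGSC	2.6	2.62			
WSYKYKKKQAWDWPWDPGSC	2.93	2.74		x	
YYNVQQVDRWVKLQWGLGSC	2.67	2.7		x	
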
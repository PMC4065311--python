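sequence	ratio_study1	ratio_study2	in_predictive	in_behavior_diagnostic	in_behavior_predictive
ADGSNWAARHWIPRMPRGSC	3.404555813	2.332923454			
AMSFHRGWDRKYRMSNIGSC	2.599608572	2.484332734			x
AQLGMYGVYRPVEIWPDGSC	2.872747926	2.519910261		x	x
ATDKTRFHFLYDYIRSNGSC	2.399571763	2.880058556			
DDTLYNAHKHLKWFGFIGSC	2.515491313	3.037141329		x	
EATGNDWVITRGGMRRYGSC	2.556966833	3.171502541			
EMNNGRFHRWAQQERHPGSC	2.880990297	2.507493739			
EMSWPRKPWRSKYYHEIGSC	2.353443025	2.435039315	x		x
ENILPTGRDRVAGWYRYGSC	2.825255829	2.675812354	x		
EPKLWFKPRRGGYRHRHGSC	2.679076813	2.434485702		x	
ERIYRDHFIHEHKANIIGSC	2.389911067	2.665777953			x
EWYYDPRGGTGSFYMRTGSC	2.826268307	3.144085944			x
FNRDHREFFEHFGFDEPGSC	4.422628739	2.314403551	x		
FPGDRRSGRAFPEVRWRGSC	2.66924554	2.635674506		x	
FTLMTGKKMIVWDWQRDGSC	2.564037604	2.381362551			x
FWEHHVFHSSRRDGWASGSC	2.951177541	2.464272834			
GLVSRIPSVPKHDEWTFGSC	2.38601487	2.329539073		x	
GRVPQDFNTPSFDRVFWGSC	2.513399666	2.788409089		x	
GWLKAMGPFPWGRLVQNGSC	2.681235945	3.008923213		x	x
IEAMGPSQRYRGRYELIGSC	2.377783579	2.371993113			
IGQRLKGKDENIRFENFGSC	2.347244686	3.594919118		x	x
ILDRRETAWNEHFSKFRGSC	2.781744911	2.979425643		x	
KAMSIHQLANPFDWHFWGSC	2.316559723	2.705671849			
KGYSIRHTEHAWPDIYVGSC	2.579657821	3.104342319			x
KLLMTDFMAKWPRNGWYGSC	3.325866727	2.467180958		x	x
KQHPIYIAHFLGTIVKRGSC	2.850248411	2.447758339			
KVDYVNQWARRRIFMAPGSC	2.933406801	2.826782754		x	
KWLQTQLNSAMYYIRLYGSC	3.442674101	2.816729922			
LAFAWKPDPWQSLVTKFGSC	3.276131888	2.698697705		x	
LFSFKEPQPFMWNKWQQGSC	3.390564552	2.759114763			
LRKISRGIWGMREAGEFGSC	2.476731381	3.603591875			
MFARAHNFDWVKWPLNRGSC	2.705759435	2.921507814			x
MWMSWGWAMLWLNGMMQGSC	4.177408974	2.432118292			
PLVHPWYPTYIPGRHNMGSC	3.630154471	2.495553997			x
PMLFWKWHRQLNQQGRRGSC	2.75721307	2.335852256		x	x
PNPEAWARSFKRWNRKFGSC	3.313709957	3.508821684			x
PSAWEWIPRNQHLNKFRGSC	3.112407959	2.391409291		x	x
PTWRLPPYTDPPKYWHPGSC	4.201093721	3.373945327			
PYRFDWAALPLKKPMWRGSC	2.40624731	2.565057719		x	
QKKPPDYRTWHHPFYNGGSC	2.604969331	2.754487673		x	
QKRWLQLPRNLMWRRETGSC	2.664022568	2.529899901		x	
QRKIFFNYKLHKIWFTAGSC	2.362843141	2.462441712			
QSHWFYDRTKDVYPGRHGSC	3.992759382	2.329563875		x	
RAAMHESLKNWRVYREWGSC	2.388166554	2.725739509		x	x
RPAFDKFADSYWYPPNLGSC	2.471919459	2.483799875			
RRLTKGIIRQYESQLWDGSC	2.38838007	3.049171397			
RTIYRWSQGALSWYMDAGSC	2.443171562	2.802208961			x
SDQVIRGFKDVWQYKWFGSC	3.018394899	2.579167723			
SRDAGLQYPYHRWLTGWGSC	2.452812911	2.732221588			
SRLEQQHFATIPQIWYTGSC	2.462810107	2.571973953			
SRQGLHYNLDGLKPIFPGSC	2.652106822	2.808739776		x	
TLQRTWRRPLLEDLPWWGSC	5.695014524	3.855075257			
VQERMHNRTWKRFGGSMGSC	2.754519694	2.496803929			x
WKPIWHSFHKRRPQILNGSC	2.50380818	2.372369774		x	x
WNGPEWKYSEKSKRILFGSC	2.445136421	2.433467124			x
WSYKYKKKQAWDWPWDPGSC	2.443311505	2.436968425		x	
WTWPSIRFVKGEEYGRFGSC	2.991053751	2.626530982			
YYNVQQVDRWVKLQWGLGSC	2.441114219	2.553038205		x	
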
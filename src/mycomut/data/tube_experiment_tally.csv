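tube,founder,kind,category,count
narrow,sh01,fate,never_reached,8
narrow,sh01,fate,reached_lost,3
narrow,sh01,fate,fixed,14
narrow,sh01,type,nonsense,0
narrow,sh01,type,nonsynonymous,1
narrow,sh01,type,synonymous,1
narrow,sh01,type,frameshift,0
narrow,sh01,type,intronic,1
narrow,sh01,type,other_noncoding,22
narrow,sh02,fate,never_reached,3
narrow,sh02,fate,reached_lost,2
narrow,sh02,fate,fixed,26
narrow,sh02,type,nonsense,0
narrow,sh02,type,nonsynonymous,6
narrow,sh02,type,synonymous,2
narrow,sh02,type,frameshift,0
narrow,sh02,type,intronic,2
narrow,sh02,type,other_noncoding,21
narrow,sh03,fate,never_reached,0
narrow,sh03,fate,reached_lost,0
narrow,sh03,fate,fixed,20
narrow,sh03,type,nonsense,0
narrow,sh03,type,nonsynonymous,5
narrow,sh03,type,synonymous,2
narrow,sh03,type,frameshift,0
narrow,sh03,type,intronic,2
narrow,sh03,type,other_noncoding,11
narrow,sh04,fate,never_reached,17
narrow,sh04,fate,reached_lost,12
narrow,sh04,fate,fixed,26
narrow,sh04,type,nonsense,0
narrow,sh04,type,nonsynonymous,10
narrow,sh04,type,synonymous,2
narrow,sh04,type,frameshift,0
narrow,sh04,type,intronic,3
narrow,sh04,type,other_noncoding,40
thick,sh01,fate,never_reached,3
thick,sh01,fate,reached_lost,1
thick,sh01,fate,fixed,11
thick,sh01,type,nonsense,0
thick,sh01,type,nonsynonymous,3
thick,sh01,type,synonymous,0
thick,sh01,type,frameshift,1
thick,sh01,type,intronic,0
thick,sh01,type,other_noncoding,11
thick,sh02,fate,never_reached,4
thick,sh02,fate,reached_lost,0
thick,sh02,fate,fixed,23
thick,sh02,type,nonsense,1
thick,sh02,type,nonsynonymous,4
thick,sh02,type,synonymous,0
thick,sh02,type,frameshift,1
thick,sh02,type,intronic,0
thick,sh02,type,other_noncoding,21
thick,sh03,fate,never_reached,4
thick,sh03,fate,reached_lost,2
thick,sh03,fate,fixed,24
thick,sh03,type,nonsense,1
thick,sh03,type,nonsynonymous,5
thick,sh03,type,synonymous,3
thick,sh03,type,frameshift,0
thick,sh03,type,intronic,1
thick,sh03,type,other_noncoding,20
thick,sh04,fate,never_reached,22
thick,sh04,fate,reached_lost,5
thick,sh04,fate,fixed,70
thick,sh04,type,nonsense,1
thick,sh04,type,nonsynonymous,11
thick,sh04,type,synonymous,6
thick,sh04,type,frameshift,1
thick,sh04,type,intronic,5
thick,sh04,type,other_noncoding,73
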
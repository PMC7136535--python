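frame,atom_index,element,q_singlet,q_triplet,q_quintuplet
0,0,Fe,1.90537986738,1.99085260758,2.20433124581
0,1,N,-0.675523562562,-0.662406159661,-0.678002568805
0,2,N,-0.195622323168,-0.163793849526,-0.172170242817
0,3,N,-0.734553533563,-0.752039812331,-0.753079326731
0,4,N,-0.231423560164,-0.251212630326,-0.258831673437
0,5,C,0.0509535579231,0.050813820766,0.0519025076958
0,6,C,-0.148175526344,-0.17057328302,-0.174690278487
0,7,C,0.0720244678617,0.0958033791075,0.0855213856912
0,8,C,0.607145111779,0.613258402411,0.619356490223
0,9,C,-0.622991747481,-0.624967957805,-0.655790792811
0,10,C,0.579249859774,0.586192900871,0.551752213555
0,11,N,0.262742353504,0.234374732725,0.183849539114
0,12,O,-0.436538719607,-0.494259333217,-0.543120374474
0,13,O,-0.432666245335,-0.452042817576,-0.461028124524
1,0,Fe,0.534780792747,0.627280602221,0.833091821469
1,1,N,-0.116897276553,-0.132802277139,-0.118338207245
1,2,N,-0.556468069948,-0.546024678611,-0.585559414167
1,3,N,-0.185030143226,-0.156640133468,-0.185950474941
1,4,N,-0.602861556655,-0.613889592286,-0.615578681768
1,5,C,0.652278990327,0.647816938558,0.647616013561
1,6,C,-0.528901493644,-0.544230090523,-0.568786544262
1,7,C,0.654686687565,0.649097406895,0.657200031157
1,8,C,0.183582008041,0.187910203161,0.192743232198
1,9,C,-0.111989445237,-0.110360772965,-0.115390265686
1,10,C,0.186441164391,0.17608883834,0.178667525814
1,11,N,-0.0919725150337,-0.107409142452,-0.17320267385
1,12,O,0.00783942448917,-0.0510973715242,-0.0868378195933
1,13,O,-0.0254885672626,-0.0257399302069,-0.0596745426884
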
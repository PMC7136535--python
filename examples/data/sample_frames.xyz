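23
frame=0
Fe       0.0367977835       0.0002938520       0.0426690895
N        1.8656414671       0.0409657345       0.0402827841
N        0.0108783659       1.9060980026      -0.0369556529
N       -1.8279201693      -0.0357731499      -0.0376828682
N        0.0656834770      -1.8610195360       0.0258173862
C        1.0161947823       2.6425493926      -0.0282326540
C        2.3192879134       2.2636223690       0.0812961126
C       -1.1013349818      -2.6599261745       0.0546188527
C       -2.2815300894      -2.2150492055       0.0129459183
C       -2.5893332917      -0.9976261732      -0.0038931799
C        2.5725534853       0.9690463443       0.0350857568
N       -0.0113523798      -0.0260161800      -2.1868198198
O        0.0289222400      -0.0199161779       3.8692261501
O        1.0065498661      -0.0410430665       4.6591837382
H        1.3686142886       3.5684451782      -0.0118527241
H        3.0718653562       2.9782013825      -0.0040795986
H       -1.4962484787      -3.5198126056       0.1082695954
H       -3.0255755531      -2.9659520457       0.1060333255
H       -3.5146123801      -1.3686275264      -0.0836968586
H        3.5786762910       1.3650939165      -0.0245747925
H        0.9411470904      -0.0332234003      -2.6143951943
H       -0.4847461057       0.8213937415      -2.5984260785
H       -0.3849505200      -0.8801276367      -2.6764686456
23
frame=1
Fe      -0.0868072404      -0.0307711579       0.1051723449
N        1.9806976953       0.0262317080      -0.0051656354
N       -0.0667524950       1.9746594683      -0.0372941119
N       -1.9892110256       0.0623577926       0.0098574248
N       -0.0305116900      -2.0459776628       0.0591378850
C        1.0806499515       2.7927078869       0.1254813635
C        2.4379679352       2.4293891135      -0.0397695958
C       -1.1023460792      -2.8553015862      -0.0489341193
C       -2.4249367274      -2.3372545800       0.0661381138
C       -2.7896970204      -1.1350206419       0.0834751385
C        2.7521469817       1.1114080112      -0.0856478229
N        0.0395416798       0.0012637912      -2.1912453476
O       -0.0342451269       0.0306328717       2.2247101606
O        0.6251868325       0.0439445077       3.3333552188
H        1.4634172128       3.7289971447       0.0333443195
H        3.1525900018       3.2306896717       0.0131914274
H       -1.4230604810      -3.8547840613      -0.0416337897
H       -3.3101261113      -3.2791788741       0.0698405433
H       -3.7761062192      -1.3620336361       0.0322061125
H        3.7550406960       1.5124495928       0.1027920844
H        0.9272814192      -0.0089802441      -2.3814644861
H       -0.4503032039       0.8238211722      -2.4935244281
H       -0.4997897190      -0.8649271325      -2.4852641874
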
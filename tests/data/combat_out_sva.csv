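X0,X1,X2,X3,X4
0.039565123807171,-0.700241198342357,0.747827685813111,1.061757522998,-1.75004099314835
-1.37116614892169,0.339010731839885,-0.200252336678731,0.228673500263009,-0.782856660445714
0.54409062801287,0.917405327077808,0.139513089273101,1.22420033191805,0.380375214294336
-0.98234548153624,0.553397890484157,-0.771432332725837,1.00770658155656,-0.0754164553294548
-0.390247869076352,-0.380717037457425,1.16742254821903,0.108824579592917,-0.408738233860656
-0.537099070586312,0.698949198113675,0.40563241488118,0.602446714892592,0.348057664813184
1.65224844988519,-0.136425407329003,-0.374457732924375,-0.464838040376013,0.511157617264159
0.763197630918164,0.123842700145215,-0.665908266272887,-0.474156389859709,0.541647390505349
1.13088580755121,0.708372250833365,-0.43229313003224,0.366528304978719,0.368983336700039
0.600102695678799,1.03604288678171,0.46040501687479,0.824176580684565,0.319354519431023
0.671368295359009,0.796344082533005,-1.22713829923492,-0.198763119509395,-0.224316430593349
-0.267628258179249,-0.10841898050812,1.7368883111598,-0.758243551410255,1.22962957641127
-1.32399434246242,-0.168051860108189,0.399316667599224,0.729224661997289,0.969844959256786
1.181572611423,-0.181866443076237,-0.228314250504024,1.00760612803373,0.0577188098667463
-0.911984656168355,-0.964985352337404,-0.687261895419512,0.637990912701433,0.394996917303754
1.07749153554402,-0.260249562645619,0.395086267248274,0.769552889495933,-0.0615783691313072
0.841011314664637,-0.494491166746818,-0.128615039561135,-0.262343568486837,-0.957496214081531
0.871566477852147,-0.302321720514904,0.248450522030432,0.621176497254701,0.702335450003374
1.05209378386421,0.0679128192340336,-0.189102954043499,0.0470422046984227,-1.45421632243281
-1.0854426741843,-1.15404931923402,-0.765370806206039,0.538229193022746,-0.66404865929037
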
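0,1,2,3,4
0.917413048922,0.135356995638,1.773451918979,1.914076867718,-1.191545986939
-0.689483537695,1.303181505045,0.706758130829,0.956710993823,-0.093554725859
1.49209394403,1.953133037307,1.089031420734,2.100753358295,1.226998543967
-0.246596493716,1.544091885961,0.064118122344,1.851962452634,0.709563290729
0.427833605622,0.494411557474,2.245542061847,0.818982669258,0.331161379552
0.260562418679,1.707650287432,1.388444787537,1.386244762923,1.190310204723
2.754343570038,0.768926085494,0.510757994101,0.159739423079,1.375468624291
1.741668261889,1.061393644223,0.18284424621,0.149030935636,1.41008198954
0.513493182766,0.102401355101,-1.049134978478,-0.132905733681,-0.168122641502
-0.011072391709,0.430675864744,-0.160029722415,0.313846506324,-0.217229381154
0.059358410252,0.190535312634,-1.840781091045,-0.684738273105,-0.755181104936
-0.868638836681,-0.715895164431,1.111316040045,-1.230898172441,0.683469903948
-1.912630760054,-0.77563794319,-0.220872206085,0.221155274612,0.42641812915
0.563586246762,-0.789477985453,-0.845977063854,0.492908824509,-0.476112775525
-1.505447311776,-1.574040127208,-1.303077557191,0.132093687306,-0.142382714573
0.46072436563,-0.868005559541,-0.225085580113,0.26052333722,-0.594154990363
0.22701424912,-1.102678854271,-0.746679117755,-0.746804950746,-1.480648096232
0.257211492348,-0.910155253407,-0.371131152462,0.115679602158,0.161722725387
0.435624120535,-0.539238397714,-0.806923583234,-0.444785267654,-1.972142884601
-1.676873460861,-1.763452525559,-1.380872098791,0.034707169976,-1.190287506003
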
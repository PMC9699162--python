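fragment,weight,al_cx,pc_cx,wc_cx
1,1,-25.3,-8.7,-9.5
2,-1,-18.1,-1.7,-6.1
3,1,-22.6,-4.8,-24.3
4,-1,-22.6,-4.7,-24.1
5,1,-22.7,-4.7,-24.2
6,-1,-4.3,-2.7,-16.3
7,1,-9.6,-18.7,-22.5
8,-1,-6.9,-18.5,-23.1
9,1,-7.3,-18.6,-23.0
10,-1,-6.5,-13.3,-3.5
11,1,-25.5,-9.7,-10.0
12,-1,-25.0,-9.4,-9.8
13,1,-26.4,-9.7,-9.5
14,-1,-19.4,2.5,-5.4
15,1,-21.8,2.7,-16.1
16,-1,-21.1,3.1,-16.0
17,1,-21.2,1.9,-16.2
18,-1,-3.6,-0.9,-10.8
19,1,-7.8,-8.6,-14.4
20,-1,-7.2,-8.7,-14.5
21,1,-7.4,-8.7,-14.5
22,-1,-4.0,-7.8,-2.9
23,1,-24.5,-9.4,-10.9
24,-1,-24.6,-8.6,-10.8
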
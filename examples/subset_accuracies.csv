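neck_4class,shoulder_4class,right_arm_4class,left_arm_4class,neck_2class,shoulder_2class,right_arm_2class,left_arm_2class
0.909,0.909,0.917,0.70,1,1,0.917,0.70
0.826,0.909,0.857,0.809,0.956,1,0.905,0.857
0.818,1,0.809,0.773,0.864,1,0.905,0.864
0.955,0.955,0.952,0.857,1,1,0.952,0.857
0.864,0.955,0.809,0.857,0.955,1,0.905,0.905
0.955,1,0.864,0.727,1,1,0.909,0.818
0.864,0.955,0.773,0.773,0.955,1,0.864,0.818
0.955,0.909,0.952,0.809,1,1,0.952,0.857
0.818,0.955,0.809,0.857,0.955,1,0.905,0.905
1,0.909,0.864,0.762,1,1,0.864,0.809
0.864,0.955,0.818,0.818,0.955,1,0.909,0.909
0.864,0.955,0.809,0.773,1,1,0.857,0.909
0.909,1,0.773,0.773,1,1,0.818,0.818
0.818,0.955,0.809,0.857,0.955,1,0.857,0.905
0.864,1,0.809,0.818,0.955,1,0.905,0.864
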
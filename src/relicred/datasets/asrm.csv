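"asrm_1","asrm_2","asrm_3","asrm_4","asrm_5"
3,2,2,1,1
3,3,2,3,2
4,3,4,3,5
3,3,1,1,4
4,3,2,2,3
2,2,1,2,2
3,3,3,2,3
4,3,4,3,4
4,4,1,3,3
4,4,2,2,4
4,3,3,2,3
5,5,2,5,5
1,1,1,1,1
3,2,1,3,3
2,2,1,1,3
2,3,2,2,4
2,3,1,2,4
3,2,2,2,3
3,3,2,3,2
3,2,1,2,3
3,3,2,3,3
3,3,2,3,3
3,3,3,3,3
1,1,1,1,1
4,3,2,3,2
2,2,1,2,1
2,3,3,4,4
3,3,1,3,3
1,1,1,3,2
3,4,2,2,4
4,3,2,2,3
2,1,3,3,4
4,3,1,3,3
3,3,3,3,3
3,3,3,1,3
3,3,2,3,4
3,2,4,3,4
2,2,1,3,2
2,2,2,2,2
2,2,2,2,3
2,2,1,2,1
2,2,2,2,2
1,1,1,1,1
3,3,3,2,3
2,3,2,3,2
3,3,3,3,3
3,3,3,3,4
2,2,2,2,2
2,3,3,4,3
4,2,2,3,3
3,3,1,3,2
2,2,1,1,1
3,3,3,3,3
2,4,2,4,3
2,2,2,2,3
1,2,1,2,2
3,3,3,3,3
2,2,2,2,2
2,2,1,2,2
3,3,2,3,2
3,3,2,2,4
3,2,3,2,4
3,3,3,3,4
2,3,1,1,3
3,4,1,2,3
2,2,4,3,3
1,1,2,2,1
2,2,1,2,2
4,3,3,4,4
4,4,2,4,3
3,2,1,3,3
4,3,3,3,3
3,3,1,2,4
3,2,1,2,3
1,1,1,3,3
2,2,1,2,4
2,4,1,3,4
2,2,2,2,2
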
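run_id,Q,t,T,Y,replicate_group
C1,0.5,32,15,0.207,C1
C1bis,0.5,32,15,0.228,C1
C2,0.5,32,35,0.204,C2
C2bis,0.5,32,35,0.224,C2
C3,0.5,92,15,0.144,C3
C3bis,0.5,92,15,0.126,C3
C4,0.5,92,35,0.090,C4
C5,0.5,62,25,0.213,C5
C6,2.5,32,35,0.495,C6
C6bis,2.5,32,35,0.470,C6
C7,2.5,32,15,0.517,C7
C8,2.5,32,15,0.517,C8
C9,2.5,92,15,0.465,C9
C9bis,2.5,92,15,0.456,C9
C10,2.5,92,35,0.350,C10
C11,2.5,62,25,0.501,C11
C12,1.5,62,25,0.389,C12
C12bis,1.5,62,25,0.403,C12
C14,1.5,62,35,0.377,C14
C15,1.5,62,15,0.407,C15
C16,1.5,92,25,0.329,C16
C17,1.5,32,25,0.470,C17
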
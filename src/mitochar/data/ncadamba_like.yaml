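# Simulation template mirroring the study system's headline structure
# at one-tenth linear scale: two circles, 14 + 69 genes, the published
# overlap pairs planted explicitly, and in-gene repeats of the kinds the
# repeat census reports. tRNA lengths are kept at natural size.
circles:
- name: circle1
  length: 10984
  at_content: 54.45
  at_skew: -0.0128
  gc_skew: -0.0241
  genes:
  - name: tRNA-Thr
    category: tRNA
    strand: N
    length: 72
  - name: orf309
    category: PCG
    strand: J
    length: 30
  - name: matR
    category: PCG
    strand: J
    length: 198
  - name: ccmFc
    category: other
    strand: N
    length: 132
    n_segments: 2
  - name: ccmFn
    category: other
    strand: J
    length: 162
  - name: nad7
    category: PCG
    strand: N
    length: 120
    n_segments: 4
  - name: atp6
    category: PCG
    strand: J
    length: 81
  - name: rpl16
    category: PCG
    strand: N
    segments:
    - - 7000
      - 7050
    length: 51
  - name: rps3
    category: PCG
    strand: N
    segments:
    - - 7040
      - 7207
    length: 168
  - name: tRNA-Tyr
    category: tRNA
    strand: N
    length: 84
  - name: tRNA-Asn
    category: tRNA
    strand: N
    length: 72
  - name: tRNA-Cys
    category: tRNA
    strand: N
    length: 72
  - name: atp9
    category: PCG
    strand: N
    length: 24
  - name: tRNA-Arg
    category: tRNA
    strand: J
    length: 71
  repeats:
  - motif: T
    copies: 10
    in_gene: orf309
  - motif: AT
    copies: 8
- name: circle2
  length: 30514
  at_content: 54.94
  at_skew: -0.0029
  gc_skew: 0.0058
  genes:
  - name: nad2
    category: PCG
    strand: N
    length: 147
    n_segments: 5
  - name: tRNA-Thr
    category: tRNA
    strand: N
    length: 72
  - name: cox2
    category: PCG
    strand: J
    length: 78
    n_segments: 2
  - name: rrn26
    category: rRNA
    strand: N
    length: 343
  - name: ccmC
    category: other
    strand: N
    length: 75
  - name: rrn5
    category: rRNA
    strand: N
    length: 30
  - name: rrn18
    category: rRNA
    strand: N
    length: 184
  - name: mttB
    category: other
    strand: J
    length: 84
  - name: tRNA-Ser
    category: tRNA
    strand: J
    length: 88
  - name: atp4
    category: PCG
    strand: N
    length: 60
  - name: nad4L
    category: PCG
    strand: N
    length: 30
  - name: tRNA-Lys
    category: tRNA
    strand: N
    length: 75
  - name: ccmB
    category: other
    strand: J
    length: 63
  - name: rpl10
    category: PCG
    strand: N
    length: 48
  - name: rps1
    category: PCG
    strand: J
    length: 60
  - name: tRNA-Met
    category: tRNA
    strand: J
    length: 77
  - name: orf954
    category: PCG
    strand: N
    length: 96
    n_segments: 3
  - name: rps13
    category: PCG
    strand: N
    length: 36
  - name: tRNA-Gly
    category: tRNA
    strand: J
    length: 74
  - name: tRNA-Gln
    category: tRNA
    strand: J
    length: 72
  - name: tRNA-Ile
    category: tRNA
    strand: N
    length: 76
  - name: atp1
    category: PCG
    strand: J
    length: 153
  - name: rpl5
    category: PCG
    strand: J
    length: 54
  - name: orf108
    category: PCG
    strand: J
    length: 12
  - name: cob
    category: PCG
    strand: J
    length: 117
  - name: rps12
    category: PCG
    strand: N
    length: 39
  - name: nad3
    category: PCG
    strand: N
    length: 36
  - name: tRNA-Val
    category: tRNA
    strand: N
    length: 60
  - name: rrn18
    category: rRNA
    strand: J
    length: 184
  - name: rrn5
    category: rRNA
    strand: J
    length: 30
  - name: ccmC
    category: other
    strand: J
    length: 75
  - name: rrn26
    category: rRNA
    strand: J
    length: 343
  - name: cox2
    category: PCG
    strand: N
    length: 78
    n_segments: 2
  - name: tRNA-Thr
    category: tRNA
    strand: J
    length: 72
  - name: tRNA-Arg
    category: tRNA
    strand: N
    length: 71
  - name: atp9
    category: PCG
    strand: J
    length: 24
  - name: nad5
    category: PCG
    strand: J
    length: 198
    n_segments: 4
  - name: tRNA-Cys
    category: tRNA
    strand: J
    length: 72
  - name: tRNA-Asn
    category: tRNA
    strand: J
    length: 72
  - name: tRNA-Tyr
    category: tRNA
    strand: J
    length: 84
  - name: rps10
    category: PCG
    strand: J
    length: 33
    n_segments: 2
  - name: cox1
    category: PCG
    strand: J
    length: 159
  - name: nad6
    category: PCG
    strand: J
    length: 63
  - name: tRNA-Val
    category: tRNA
    strand: J
    length: 60
  - name: nad3
    category: PCG
    strand: J
    length: 36
  - name: rps12
    category: PCG
    strand: J
    length: 39
  - name: cob
    category: PCG
    strand: N
    length: 117
  - name: orf108
    category: PCG
    strand: N
    length: 12
  - name: rpl5
    category: PCG
    strand: N
    length: 54
  - name: atp1
    category: PCG
    strand: N
    length: 153
  - name: tRNA-Ile
    category: tRNA
    strand: J
    length: 76
  - name: tRNA-Gln
    category: tRNA
    strand: N
    length: 72
  - name: tRNA-Gly
    category: tRNA
    strand: N
    length: 74
  - name: atp8
    category: PCG
    strand: J
    length: 48
  - name: cox3
    category: PCG
    strand: J
    segments:
    - - 21000
      - 21080
    length: 81
  - name: sdh4
    category: PCG
    strand: J
    segments:
    - - 21074
      - 21118
    length: 45
  - name: rps4
    category: PCG
    strand: N
    segments:
    - - 24000
      - 24083
    length: 84
  - name: tRNA-Leu
    category: tRNA
    strand: J
    segments:
    - - 24005
      - 24069
    length: 65
  - name: rpl2
    category: PCG
    strand: J
    length: 99
    n_segments: 3
  - name: tRNA-Ala
    category: tRNA
    strand: J
    length: 65
  - name: tRNA-Trp
    category: tRNA
    strand: N
    length: 74
  - name: nad9
    category: PCG
    strand: N
    length: 57
  - name: tRNA-His
    category: tRNA
    strand: N
    length: 75
  - name: tRNA-Glu
    category: tRNA
    strand: J
    length: 72
  - name: tRNA-Ser
    category: tRNA
    strand: J
    length: 88
  - name: tRNA-Phe
    category: tRNA
    strand: J
    length: 74
  - name: tRNA-Pro
    category: tRNA
    strand: J
    length: 75
  - name: tRNA-Asp
    category: tRNA
    strand: N
    length: 74
  - name: nad4
    category: PCG
    strand: J
    length: 150
    n_segments: 4
  repeats:
  - motif: A
    copies: 10
    in_gene: atp1
  - motif: AT
    copies: 8
  - motif: GA
    copies: 6
  - motif: ACGTTGCAAGTCCAT
    copies: 4
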
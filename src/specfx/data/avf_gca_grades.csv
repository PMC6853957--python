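indicator,rank,peak_id,grade
ALT,1,P1,0.826
ALT,2,P12,0.806
ALT,3,P8,0.791
ALT,4,P9,0.788
ALT,5,P5,0.772
ALT,6,P2,0.768
ALT,7,P3,0.759
ALT,8,P10,0.705
ALT,9,P11,0.701
ALT,10,P4,0.686
ALT,11,P6,0.660
ALT,12,P7,0.581
ALT,1,N12,0.831
ALT,2,N3,0.803
ALT,3,N4,0.776
ALT,4,N5,0.769
ALT,5,N11,0.759
ALT,6,N9,0.752
ALT,7,N6,0.748
ALT,8,N7,0.747
ALT,9,N10,0.743
ALT,10,N1,0.721
ALT,11,N13,0.712
ALT,12,N8,0.658
ALT,13,N14,0.581
ALT,14,N2,0.555
AST,1,P4,0.902
AST,2,P5,0.885
AST,3,P8,0.880
AST,4,P10,0.857
AST,5,P11,0.842
AST,6,P2,0.840
AST,7,P12,0.825
AST,8,P6,0.809
AST,9,P1,0.808
AST,10,P3,0.782
AST,11,P9,0.773
AST,12,P7,0.755
AST,1,N1,0.914
AST,2,N4,0.902
AST,3,N12,0.876
AST,4,N3,0.866
AST,5,N10,0.848
AST,6,N6,0.846
AST,7,N8,0.819
AST,8,N2,0.795
AST,9,N11,0.794
AST,10,N9,0.767
AST,11,N5,0.736
AST,12,N7,0.706
AST,13,N14,0.679
AST,14,N13,0.631
MDA,1,P5,0.939
MDA,2,P8,0.921
MDA,3,P10,0.909
MDA,4,P4,0.901
MDA,5,P11,0.890
MDA,6,P2,0.868
MDA,7,P12,0.830
MDA,8,P1,0.823
MDA,9,P6,0.803
MDA,10,P3,0.797
MDA,11,P9,0.780
MDA,12,P7,0.754
MDA,1,N1,0.957
MDA,2,N4,0.923
MDA,3,N10,0.894
MDA,4,N12,0.873
MDA,5,N8,0.869
MDA,6,N3,0.858
MDA,7,N6,0.843
MDA,8,N11,0.829
MDA,9,N9,0.785
MDA,10,N2,0.741
MDA,11,N5,0.739
MDA,12,N7,0.679
MDA,13,N14,0.669
MDA,14,N13,0.623
SOD,1,P1,0.934
SOD,2,P2,0.928
SOD,3,P3,0.894
SOD,4,P11,0.876
SOD,5,P5,0.875
SOD,6,P8,0.873
SOD,7,P9,0.856
SOD,8,P10,0.803
SOD,9,P7,0.783
SOD,10,P6,0.771
SOD,11,P4,0.746
SOD,12,P12,0.739
SOD,1,N9,0.872
SOD,2,N10,0.861
SOD,3,N3,0.835
SOD,4,N6,0.825
SOD,5,N11,0.825
SOD,6,N4,0.807
SOD,7,N5,0.792
SOD,8,N1,0.778
SOD,9,N8,0.777
SOD,10,N12,0.727
SOD,11,N14,0.706
SOD,12,N13,0.639
SOD,13,N2,0.620
SOD,14,N7,0.615
CAT,1,P5,0.948
CAT,2,P8,0.931
CAT,3,P11,0.912
CAT,4,P2,0.877
CAT,5,P4,0.869
CAT,6,P10,0.841
CAT,7,P12,0.828
CAT,8,P1,0.814
CAT,9,P3,0.797
CAT,10,P6,0.789
CAT,11,P9,0.765
CAT,12,P7,0.724
CAT,1,N10,0.948
CAT,2,N4,0.908
CAT,3,N1,0.904
CAT,4,N6,0.893
CAT,5,N8,0.892
CAT,6,N11,0.878
CAT,7,N3,0.858
CAT,8,N12,0.832
CAT,9,N9,0.822
CAT,10,N5,0.722
CAT,11,N2,0.665
CAT,12,N7,0.665
CAT,13,N14,0.638
CAT,14,N13,0.607
POD,1,P2,0.944
POD,2,P11,0.936
POD,3,P5,0.897
POD,4,P1,0.885
POD,5,P8,0.883
POD,6,P3,0.849
POD,7,P9,0.820
POD,8,P10,0.818
POD,9,P4,0.791
POD,10,P7,0.771
POD,11,P6,0.765
POD,12,P12,0.764
POD,1,N10,0.963
POD,2,N1,0.946
POD,3,N8,0.933
POD,4,N11,0.929
POD,5,N6,0.911
POD,6,N4,0.910
POD,7,N9,0.896
POD,8,N5,0.870
POD,9,N13,0.869
POD,10,N3,0.863
POD,11,N14,0.830
POD,12,N12,0.827
POD,13,N7,0.718
POD,14,N2,0.590
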
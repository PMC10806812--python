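imidazolidin-2-ylidene
     RDKit          2D

  5  5  0  0  0  0  0  0  0  0999 V2000
    1.2760    0.0000    0.0000 C   0  0  0  0  0  2  0  0  0  0  0  0
    0.3943    1.2135    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0323    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0323   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3943   -1.2135    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  5  1  1  0
M  RAD  1   1   3
M  END
>  <ROLE>  (1) 
scaffold

>  <ATTACHMENT_POINTS>  (1) 
1 n_aryl 1
4 n_aryl 1
2 backbone 1
3 backbone 1
2 backbone 1
3 backbone 1

$$$$
phenyl
     RDKit          2D

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
M  END
>  <ROLE>  (2) 
substituent

>  <ATTACHMENT_POINTS>  (2) 
0 aryl_ipso 1
1 ortho 1
5 ortho 1
3 para 1

$$$$
methyl
     RDKit          2D

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
>  <ROLE>  (3) 
substituent

>  <ATTACHMENT_POINTS>  (3) 
0 r_alkyl 1

$$$$
ethyl
     RDKit          2D

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
>  <ROLE>  (4) 
substituent

>  <ATTACHMENT_POINTS>  (4) 
0 r_backbone_alkyl 1

$$$$
isopropyl
     RDKit          2D

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5981   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
>  <ROLE>  (5) 
substituent

>  <ATTACHMENT_POINTS>  (5) 
1 r_alkyl 1

$$$$
tert-butyl
     RDKit          2D

  4  3  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5981   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990    2.2500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  1  0
M  END
>  <ROLE>  (6) 
substituent

>  <ATTACHMENT_POINTS>  (6) 
1 r_alkyl 1

$$$$
acetyl
     RDKit          2D

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5981   -0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
M  END
>  <ROLE>  (7) 
substituent

>  <ATTACHMENT_POINTS>  (7) 
1 r_acyl 1

$$$$
methoxycarbonyl
     RDKit          2D

  4  3  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990    0.7500    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    2.5981   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.8971    0.7500    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
M  END
>  <ROLE>  (8) 
substituent

>  <ATTACHMENT_POINTS>  (8) 
2 r_acyl 1

$$$$
dimethylamino
     RDKit          2D

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990    0.7500    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    2.5981   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
>  <ROLE>  (9) 
substituent

>  <ATTACHMENT_POINTS>  (9) 
1 r_amino 1

$$$$
nitro
     RDKit          2D

  3  2  0  0  0  0  0  0  0  0999 V2000
    1.2990    0.7500    0.0000 O   0  0  0  0  0  1  0  0  0  0  0  0
    0.0000    0.0000    0.0000 N   0  0  0  0  0  4  0  0  0  0  0  0
   -1.2990    0.7500    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
M  CHG  2   1  -1   2   1
M  END
>  <ROLE>  (10) 
substituent

>  <ATTACHMENT_POINTS>  (10) 
1 r_nitro 1

$$$$
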
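      32
       2        4
      11        0      864
       0      186        0        0
       0      246        8       49        0
       0        0        0      569        0      274
      78       18       47       79        0        0       22
       8      232      458       11      305      550       22        0
      75        0       19        0       41        0        0        0        0
      21        6        0        0       27       20        0        0       26      232
       0       50      408        0        0      242      215        0        0        6        4
      76        0       21        0        0       22        0        0        0      378      609       59
       0        0        6        5        7        0        0        0        0       57      246        0       11
      53        9       33        2        0       51        0        0       53        5       43       18        0       17
     342        3      446       16      347       30       21      112       20        0       74       65       47       90      202
     681        0      110        0      114        0        4        0        1      360       34       50      691        8       78      614
       5       16        6        0       65        0        0        0        0        0       12        0       13        0        7       17        0
       0        0      156        0      530       54        0        1     1525       16       25       67        0      682        8      107        0       14
     398        0        0       10        0       33       20        5        0     2220      100        0      832        6        0        0      237        0        0

  0.0692   0.0184     0.04   0.0186   0.0065   0.0238   0.0236   0.0557   0.0277   0.0905   0.1675   0.0221   0.0561   0.0611   0.0536   0.0725    0.087   0.0293    0.034   0.0428
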
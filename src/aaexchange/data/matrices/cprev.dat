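     105
     227      357
     175       43     4435
     669      823      538       10
     157     1745      768      400       10
     499      152     1055     3691       10     3122
     665      243      653      431      303      133      379
      66      715     1405      331      441     1269      162       19
     145      136      168       10      280       92      148       40       29
     197      203      113       10      396      286       82       20       66     1745
     236     4482     2430      412       48     3313     2629      263      305      345      218
     185      125       61       47      159      202      113       21       10     1772     1351      193
      68       53       97       22      726       10      145       25      127      454     1268       72      327
     490       87      173      170      285      323      185       28      152      117      219      302      100       43
    2440      385     2085      590     2331      396      568      691      303      216      516      868       93      487     1202
    1340      314     1393      266      576      241      369       92       32     1040      156      918      645      148      260     2151
      14      230       40       18      435       53       63       82       69       42      159       10       86      468       49       73       29
      56      323      754      281     1466      391      142       10     1971       89      189      247      215     2370       97      522       71      346
     968       92       83       75      592       54      200       91       25     4797      865      249      475      317      122      167      760       10      119

  0.0755   0.0621    0.041   0.0371   0.0091   0.0382   0.0495   0.0838   0.0246   0.0806   0.1011   0.0504    0.022   0.0506   0.0431   0.0622   0.0543   0.0181   0.0307    0.066
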
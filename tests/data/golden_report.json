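{
 "anomalies": {
  "anomaly": [
   -0.31476556764592084,
   -0.15500805427422706,
   0.10832276904859765,
   1.5642819162198318,
   -0.5734415658595857,
   -0.6293894974886961
  ],
  "column_id": [
   "colA",
   "colA",
   "colA",
   "colA",
   "colA",
   "colA"
  ],
  "signal": [
   "Desulfobacula toluolica Tol2",
   "Desulfobacula toluolica Tol2",
   "Desulfobacula toluolica Tol2",
   "Desulfobacula toluolica Tol2",
   "Desulfobacula toluolica Tol2",
   "Desulfobacula toluolica Tol2"
  ],
  "time_point": [
   0,
   2,
   4,
   6,
   8,
   10
  ],
  "window_mean": [
   10.14379913889768,
   10.14379913889768,
   10.14379913889768,
   10.14379913889768,
   10.14379913889768,
   10.14379913889768
  ]
 },
 "columns": {
  "colA": {
   "critical_time_points": [
    6
   ],
   "kruskal": [
    4.857142857142854,
    0.3022720778137972
   ],
   "phase_cells": {
    "CT": [
     3901734.1040462432
    ],
    "M": [
     346153.8461538462
    ],
    "R": [
     281954.88721804507
    ],
    "S": [
     660333.6422613531,
     942857.1428571428
    ],
    "TM": [
     1349112.426035503
    ]
   },
   "ssp_rank": [
    [
     "Desulfobacula toluolica Tol2",
     18.62708212196874
    ]
   ]
  }
 }
}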
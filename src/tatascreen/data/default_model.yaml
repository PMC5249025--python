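bend_weights:
  AA: 0.0
  AC: 0.0
  AG: 0.0
  AT: 0.0
  CA: 0.0
  CC: 0.0
  CG: 0.0
  CT: 0.0
  GA: 0.0
  GC: 0.0
  GG: 0.0
  GT: 0.0
  TA: 1.0
  TC: 0.5
  TG: 0.5
  TT: 0.25
delta_constant: 0.042749999999999996
delta_method: constant
format_version: 1
linear_coeffs:
  bending: 0.1861075854162473
  intercept: 17.91345740524886
  recognition: 1.0
  sliding: -0.39830646742043124
pwm:
- A: 0.6232009400425729
  C: -1.2222687539361914
  G: -0.8648979526049785
  T: 0.6562183300646776
- A: 0.44059381434800127
  C: -0.8382806559216136
  G: 1.3380586476339928
  T: -1.748119242498278
- A: -0.8513308592055256
  C: 0.32989694033523104
  G: -0.8606496213401187
  T: 0.5743361037752694
- A: 0.16960347816232513
  C: 0.06503306394740302
  G: 0.7545138614620978
  T: -1.7968978400089237
- A: -0.08475793770911634
  C: -0.579828130656364
  G: -0.747629218510553
  T: 0.20446785044079582
- A: -0.12466964375183301
  C: -0.4083156949792915
  G: 1.4962469064273154
  T: -2.1710090041283086
- A: -2.9358429710710383
  C: 0.05363137952913909
  G: 0.7757349000239768
  T: 0.8987292550817871
- A: 0.02507608006782383
  C: -0.4067512797557106
  G: -1.29920627144392
  T: 0.47313403469710213
- A: -0.14135914314504186
  C: -0.5195213273702026
  G: -0.2969762657058609
  T: 0.35010929978604893
- A: 0.22537652957293003
  C: 0.8763388854358415
  G: -1.0270100709185237
  T: -1.182452780524243
- A: 0.2142262355980286
  C: -0.31780047031326897
  G: -0.5317811033793313
  T: 0.027607901658374817
- A: 0.4501610049816383
  C: -1.8957243244301956
  G: 1.2063460358436118
  T: -0.3685301528301858
- A: 1.166706705055698
  C: 0.41083045483382635
  G: 1.1348929837781851
  T: -3.5201775800998267
- A: -0.04972170131188047
  C: -1.191071733314188
  G: -1.344316129159976
  T: 1.7773621273543285
- A: -1.0307341553992553
  C: 0.4777383199166701
  G: -0.45428627586092
  T: 0.1995346749098105
slide_weights:
  AA: 1.0
  AC: 1.44
  AG: 1.28
  AT: 0.88
  CA: 1.45
  CC: 1.84
  CG: 2.17
  CT: 1.28
  GA: 1.3
  GC: 2.24
  GG: 1.84
  GT: 1.44
  TA: 0.58
  TC: 1.3
  TG: 1.45
  TT: 1.0
window_length: 26
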
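diet:
  intake: 10.0
  delta15N: 3.5
compartments:
- id: St
  label: stomach lumen
  subsystem: absorptive
  fraction: luminal-N
- id: SIl
  label: small-intestine lumen
  subsystem: absorptive
  fraction: luminal-N
- id: CC
  label: caeco-colonic lumen
  subsystem: absorptive
  fraction: luminal-N
- id: SIp
  label: SI mucosa protein
  subsystem: splanchnic
  fraction: protein
- id: SIa
  label: SI mucosa free AA
  subsystem: splanchnic
  fraction: free-AA
- id: Lp
  label: liver protein
  subsystem: splanchnic
  fraction: protein
- id: La
  label: liver free AA
  subsystem: splanchnic
  fraction: free-AA
- id: Plp
  label: plasma protein
  subsystem: peripheral
  fraction: protein
- id: Pla
  label: plasma free AA
  subsystem: peripheral
  fraction: free-AA
- id: Mp
  label: muscle protein
  subsystem: peripheral
  fraction: protein
- id: Ma
  label: muscle free AA
  subsystem: peripheral
  fraction: free-AA
- id: Kp
  label: kidney protein
  subsystem: peripheral
  fraction: protein
- id: Ka
  label: kidney free AA
  subsystem: peripheral
  fraction: free-AA
- id: Hp
  label: heart protein
  subsystem: peripheral
  fraction: protein
- id: Ha
  label: heart free AA
  subsystem: peripheral
  fraction: free-AA
- id: Rp
  label: RBC protein
  subsystem: peripheral
  fraction: protein
- id: Ra
  label: RBC free AA
  subsystem: peripheral
  fraction: free-AA
- id: Skp
  label: skin protein
  subsystem: peripheral
  fraction: protein
- id: Ska
  label: skin free AA
  subsystem: peripheral
  fraction: free-AA
- id: Hair
  label: hair
  subsystem: peripheral
  fraction: protein
- id: U
  label: body urea
  subsystem: urea
  fraction: urea
fluxes:
- id: diet
  source: DIET
  target: St
  k: 10.0
  epsilon: 0.0
- id: tSt
  source: St
  target: SIl
  k: 16.666666666666668
  epsilon: 0.0
- id: tSI
  source: SIl
  target: CC
  k: 1.0
  epsilon: 0.0
- id: absSI
  source: SIl
  target: SIa
  k: 9.0
  epsilon: 0.0
- id: secSI
  source: SIa
  target: SIl
  k: 14.285714285714286
  epsilon: 0.6000000000000039
- id: PV
  source: SIa
  target: La
  k: 22.44777930776951
  epsilon: 0.0
- id: absCC
  source: CC
  target: La
  k: 1.4437500000000003
  epsilon: -0.5685425685425706
- id: UH
  source: U
  target: CC
  k: 0.7500000000000003
  epsilon: 0.0
- id: UE
  source: U
  target: SINK
  k: 3.4166666666666674
  epsilon: 0.5999999999999999
- id: NH4
  source: La
  target: SINK
  k: 0.31875
  epsilon: -1.8500000000000003
- id: FL
  source: CC
  target: SINK
  k: 0.6187499999999999
  epsilon: 0.0
- id: lHa
  source: Hair
  target: SINK
  k: 0.014285714285714287
  epsilon: 0.0
- id: lSk
  source: Skp
  target: SINK
  k: 0.0019230769230769232
  epsilon: 0.0
- id: sSI
  source: SIa
  target: SIp
  k: 4.500000000000001
  epsilon: 2.0000000000000013
- id: dSI
  source: SIp
  target: SIa
  k: 1.5
  epsilon: 0.0
- id: oxSI
  source: SIa
  target: U
  k: 1.8379349779447807
  epsilon: -4.663619047619113
- id: sL
  source: La
  target: Lp
  k: 3.875
  epsilon: 2.100000000000006
- id: dL
  source: Lp
  target: La
  k: 0.5
  epsilon: 0.0
- id: oxL
  source: La
  target: U
  k: 1.7230640418232315
  epsilon: -3.0243906429748417
- id: inL
  source: Pla
  target: La
  k: 21.94138789317393
  epsilon: 0.0
- id: outL
  source: La
  target: Pla
  k: 15.625
  epsilon: 0.0
- id: sPl
  source: La
  target: Plp
  k: 0.34375
  epsilon: 2.8500000000000005
- id: dPl
  source: Plp
  target: Pla
  k: 0.25
  epsilon: 0.0
- id: sHa
  source: Ska
  target: Hair
  k: 0.08333333333333334
  epsilon: 0.0
- id: sM
  source: Ma
  target: Mp
  k: 1.9
  epsilon: 4.799999999999996
- id: dM
  source: Mp
  target: Ma
  k: 0.10999999999999999
  epsilon: 0.0
- id: oxM
  source: Ma
  target: U
  k: 0.7760169906877962
  epsilon: 3.839972260672668
- id: inM
  source: Pla
  target: Ma
  k: 18.441176470588236
  epsilon: 0.0
- id: outM
  source: Ma
  target: Pla
  k: 2.073983009312204
  epsilon: 0.0
- id: sK
  source: Ka
  target: Kp
  k: 2.986666666666667
  epsilon: 0.5999999999999978
- id: dK
  source: Kp
  target: Ka
  k: 0.42
  epsilon: 0.0
- id: oxK
  source: Ka
  target: U
  k: 1.2198442520285357
  epsilon: -2.4034477393273397
- id: inK
  source: Pla
  target: Ka
  k: 2.371764705882353
  epsilon: 0.0
- id: outK
  source: Ka
  target: Pla
  k: 3.260155747971464
  epsilon: 0.0
- id: sH
  source: Ha
  target: Hp
  k: 1.7272727272727273
  epsilon: 4.1000000000000005
- id: dH
  source: Hp
  target: Ha
  k: 0.2
  epsilon: 0.0
- id: oxH
  source: Ha
  target: U
  k: 0.7054699915343602
  epsilon: -1.6689277393273447
- id: inH
  source: Pla
  target: Ha
  k: 0.6705882352941177
  epsilon: 0.0
- id: outH
  source: Ha
  target: Pla
  k: 1.885439099374731
  epsilon: 0.0
- id: sR
  source: Ra
  target: Rp
  k: 0.3136363636363636
  epsilon: 3.0000000000000013
- id: dR
  source: Rp
  target: Ra
  k: 0.03
  epsilon: 0.0
- id: oxR
  source: Ra
  target: U
  k: 0.128098498462818
  epsilon: -1.3016677393273444
- id: inR
  source: Pla
  target: Ra
  k: 0.6088235294117647
  epsilon: 0.0
- id: outR
  source: Ra
  target: Pla
  k: 0.3423560469917274
  epsilon: 0.0
- id: sSk
  source: Ska
  target: Skp
  k: 1.516666666666667
  epsilon: 2.0000000000000018
- id: dSk
  source: Skp
  target: Ska
  k: 0.06807692307692309
  epsilon: 0.0
- id: oxSk
  source: Ska
  target: U
  k: 0.6194521592332409
  epsilon: -2.3957262668354
- id: inSk
  source: Pla
  target: Ska
  k: 3.4258823529411777
  epsilon: 0.0
- id: outSk
  source: Ska
  target: Pla
  k: 0.46888117410009295
  epsilon: 0.0
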
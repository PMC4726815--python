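k.ampar-grip.on:
  value: 0.0015
  provenance: default
k.ampar-grip.off:
  value: 0.005
  provenance: default
k.ampar-grip.offpS:
  value: 1.0
  provenance: default
k.ampar-pick.on:
  value: 0.0003
  provenance: default
k.ampar-pick.on*:
  value: 0.0012
  provenance: default
k.ampar-pick.off:
  value: 0.05
  provenance: default
k.grip-pick.on:
  value: 5.0e-05
  provenance: default
k.grip-pick.off:
  value: 0.05
  provenance: default
k.ansf.on:
  value: 0.001
  provenance: default
k.ansf.off:
  value: 0.02
  provenance: default
k.diff.psd-x:
  value: 0.05
  provenance: default
k.diff.x-psd:
  value: 0.2
  provenance: default
k.diff.x-ez:
  value: 0.2
  provenance: default
k.diff.ez-x:
  value: 0.008
  provenance: default
k.endo:
  value: 0.1
  provenance: default
k.exo:
  value: 0.014
  provenance: default
pkc.act:
  value: 0.0
  provenance: default
pkc.deact:
  value: 0.0
  provenance: default
k.pick-pkc.on:
  value: 0.0005
  provenance: default
k.pick-pkc.off:
  value: 0.05
  provenance: default
kcat.pkc:
  value: 1.0
  provenance: default
km.pkc:
  value: 50.0
  provenance: default
kcat.pp2a:
  value: 2.0
  provenance: default
km.pp2a:
  value: 50.0
  provenance: default
kcat.sfk:
  value: 2.0
  provenance: default
km.sfk:
  value: 500.0
  provenance: default
kcat.ptpmeg:
  value: 0.32
  provenance: default
km.ptpmeg:
  value: 10.0
  provenance: default
init.ampar.membrane:
  value: 125.0
  provenance: default
init.ampar.endosome:
  value: 125.0
  provenance: default
init.pkc:
  value: 20.0
  provenance: default
init.pp2a:
  value: 20.0
  provenance: default
init.sfk:
  value: 10.0
  provenance: default
init.ptpmeg:
  value: 10.0
  provenance: default
init.grip:
  value: 300.0
  provenance: default
init.pick1:
  value: 200.0
  provenance: default
init.nsf:
  value: 200.0
  provenance: default
geometry.depth:
  value: 0.12
  provenance: default
geometry.area:
  value: 8.3333333333333
  provenance: default
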
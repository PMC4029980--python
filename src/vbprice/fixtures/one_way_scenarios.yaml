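# One-way sensitivity scenarios for the sorafenib vs BSC analysis.
# 'scale' on survival effects is the factor on median time-to-event
# (1.1 = 10% longer; hazards divided by 1.1).
scenarios:
  - {name: "sorafenib price -50%", target: price, kind: scale, value: 0.5}
  - {name: "time horizon 5 years", target: horizon, kind: set, value: 60}
  - {name: "discount 0%", target: discount, kind: set, value: 0.0}
  - {name: "discount 1.5%", target: discount, kind: set, value: 0.015}
  - {name: "discount 5%", target: discount, kind: set, value: 0.05}
  - {name: "utilities +10%", target: utilities, kind: scale, value: 1.1}
  - {name: "utilities -10%", target: utilities, kind: scale, value: 0.9}
  - {name: "medical costs +20%", target: medical_costs, kind: scale, value: 1.2}
  - {name: "medical costs -20%", target: medical_costs, kind: scale, value: 0.8}
  - {name: "PFS and OS +10%", target: pfs_os_effect, kind: scale, value: 1.1}
  - {name: "OS +10%", target: os_effect, kind: scale, value: 1.1}
  - {name: "PFS +10%", target: pfs_effect, kind: scale, value: 1.1}
  - {name: "PFS and OS -10%", target: pfs_os_effect, kind: scale, value: 0.9}
  - {name: "OS -10%", target: os_effect, kind: scale, value: 0.9}
  - {name: "PFS -10%", target: pfs_effect, kind: scale, value: 0.9}
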
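# Consensus compliance targets for the ten proxy indicators.
# direction: lower = lower values are better, higher = higher values are better.
# Bounds are {op, value}; op is one of <, <=, >, >=, ==.  A value meeting the
# optimal bound classifies optimal; else meeting the acceptable bound
# classifies acceptable; else non_compliant.  Comparisons are strict or
# inclusive exactly as printed in the consensus target.
PI1:
  direction: lower
  optimal: {op: "==", value: 0}
  acceptable: {op: "<", value: 0.2}
PI2:
  direction: higher
  optimal: {op: ">", value: 1.5}
PI3:
  direction: lower
  optimal: {op: "==", value: 0}
  acceptable: {op: "<", value: 10}
PI4:
  direction: lower
  optimal: {op: "<", value: 20}
PI5:
  direction: lower
  optimal: {op: "<", value: 20}
PI6:
  direction: higher
  optimal: {op: ">", value: 1.5}
PI7:
  direction: lower
  optimal: {op: "<", value: 5}
  acceptable: {op: "<", value: 20}
PI8:
  direction: lower
  optimal: {op: "==", value: 0}
  acceptable: {op: "<", value: 5}
PI9:
  direction: higher
  optimal: {op: ">=", value: 90}
PI10:
  direction: lower
  optimal: {op: "<", value: 10}
  acceptable: {op: "<", value: 30}
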
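# Offsets of (observation day - hatch day) per behavioural atlas code,
# derived from stage durations: nest building 8 d, incubation 14 d,
# nestling period 20 d, fledgling dependence 14 d.  Edit to match a local
# atlas-code catalogue; every code occurring in the data needs an entry.
nest_building: [-22, -14]
incubation: [-14, 0]
food_for_young: [0, 20]
fledglings: [20, 34]
hatch: [0, 0]   # direct hatching observation (systematic brood monitoring)
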
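# Default personalized-recommendation rules.
#
# These encode standard behavioral sleep-medicine heuristics and are a
# package default, fully replaceable by deployment configuration.  Units:
# minutes for sol/waso/twak/tib/tst, percent for se, counts for nwak.
# Lower priority = more important; fired rules are ordered by
# (priority, id).
rules:
  - id: severe-complaints-note
    when: "isi_total > 21"
    advice: consult_specialist_note
    priority: 0

  - id: restrict-time-in-bed
    when: "se < 85 and tib > 540"
    advice: restrict_tib
    priority: 1
    params:
      reduce_minutes: 30

  - id: stimulus-control
    when: "sol > 30"
    advice: stimulus_control
    priority: 2
    params:
      leave_bed_after_minutes: 20

  - id: fixed-rise-time
    when: "twak > 30"
    advice: fixed_rise_time
    priority: 3

  - id: wind-down-routine
    when: "waso > 30 or nwak > 2"
    advice: wind_down
    priority: 4

  - id: morning-light-low-efficiency
    when: "se < 80"
    advice: morning_light
    priority: 5
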
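# Advice template catalog: every advice id emitted by the engine resolves
# to a template here.  Placeholders in {braces} are filled from rule params.
advice:
  regular_wake_time: "Keep your usual wake-up time every day, including weekends."
  morning_light: "Get exposed to sunlight in the morning."
  quiet_dark_room: "Sleep in a quiet and dark room."
  restrict_tib: "Reduce your time in bed by about {reduce_minutes} minutes: go to bed later, keep your wake-up time."
  stimulus_control: "If you are not asleep after about {leave_bed_after_minutes} minutes, leave the bed and return only when sleepy."
  fixed_rise_time: "Get out of bed at a fixed time soon after your final awakening."
  wind_down: "Set up a calm wind-down routine before bed; avoid screens, caffeine and alcohol in the evening."
  consult_specialist_note: "Your complaints remain severe; a consultation with a sleep specialist is recommended."
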
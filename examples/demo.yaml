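# Small demonstration cohort: full pipeline in under a minute.
seed: 1
out_dir: musemind_demo
n_participants: 4
timeline:
  order: music_first
  baseline_dur: 240
  section_dur: 300
  inter_gap: 60
post_shift:
  suds: -1.0
  sms: 0.5
  asc: 10.0
  scs: 0.5
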
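n_patients: 1581
seed: 0
gmfcs_probs:
- 0.07463630613535736
- 0.1827956989247312
- 0.37444655281467426
- 0.2972802024035421
- 0.07084123972169513
gmfm_level_means:
- 85.0
- 65.0
- 50.0
- 35.0
- 15.0
gmfm_level_sd: 8.0
age_mean: 8.1
age_sd: 4.3
age_range:
- 2.2
- 25.5
female_prob: 0.41492726122707146
subtype_probs_by_level:
- - 0.5005005005005005
  - 0.3983983983983984
  - 0.025025025025025027
  - 0.025025025025025027
  - 0.05105105105105105
- - 0.758
  - 0.121
  - 0.017
  - 0.042
  - 0.062
- - 0.821
  - 0.035
  - 0.037000000000000005
  - 0.017
  - 0.09
- - 0.774
  - 0.015
  - 0.077
  - 0.011000000000000001
  - 0.12300000000000001
- - 0.607
  - 0.0
  - 0.223
  - 0.009000000000000001
  - 0.161
device_profiles:
- code: transtibial_orthosis
  label: Transtibial orthoses
  base_rate: 0.3556932290802008
  score_center: 55.0
  score_width: 22.0
- code: active_wheelchair
  label: Active wheelchair
  base_rate: 0.45464628007551094
  score_center: 38.0
  score_width: 14.0
- code: posterior_walker
  label: Posterior walker
  base_rate: 0.34272054439755306
  score_center: 45.0
  score_width: 12.0
- code: standing_frame
  label: Standing frame
  base_rate: 0.3356152767678273
  score_center: 30.0
  score_width: 14.0
- code: night_splint
  label: Night splints
  base_rate: 0.1911335995880877
  score_center: 52.0
  score_width: 18.0
- code: shoe_insert
  label: Shoe inserts
  base_rate: 0.3058905052280823
  score_center: 71.0
  score_width: 16.0
- code: passive_wheelchair
  label: Passive wheelchair
  base_rate: 0.7599837712873967
  score_center: 18.0
  score_width: 10.0
- code: hand_orthosis
  label: Hand orthoses
  base_rate: 0.15722579685532134
  score_center: 47.0
  score_width: 20.0
- code: roller_board
  label: Roller board
  base_rate: 0.4462142517025628
  score_center: 25.0
  score_width: 10.0
- code: therapy_bike
  label: Therapy bike with training wheels
  base_rate: 0.6291237521641955
  score_center: 84.0
  score_width: 14.0
- code: seating_shell
  label: Seating shell
  base_rate: 0.5817065481941885
  score_center: 22.0
  score_width: 9.0
- code: walking_frame
  label: Walking frame
  base_rate: 0.16637958459355554
  score_center: 42.0
  score_width: 12.0
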
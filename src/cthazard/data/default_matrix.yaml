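beat_stop:
  partial_boundary: 0.5
  points_complete: 4
  points_partial_high: 2
  points_partial_low: 1
fibrillation_points: 4
label_ranges:
- label: 'no'
  max_score: 0
  min_score: 0
- label: low
  max_score: 2
  min_score: 1
- label: high
  max_score: null
  min_score: 3
parameters:
  amp:
    cutoffs:
      mild_down: -25.501707094414837
      mild_up: 20.4690886020523
      no_effect_high: 6.3267247118348475
      no_effect_low: -6.3267247118348475
      strong_down: -44.676689476994824
      strong_up: 34.61145249226975
    points:
      mild_down: 1
      mild_up: 1
      no_effect: 0
      strong_down: 2
      strong_up: 2
  br:
    cutoffs:
      mild_down: -22.78446936145565
      mild_up: 29.94570590542699
      no_effect_high: 10.644845453124521
      no_effect_low: -10.644845453124521
      strong_down: -34.92409326978678
      strong_up: 49.246566357729456
    points:
      mild_down: 1
      mild_up: 1
      no_effect: 0
      strong_down: 2
      strong_up: 2
  ctd90:
    cutoffs:
      mild_down: -20.073626515441
      mild_up: 26.95124602371716
      no_effect_high: 7.067525023282535
      no_effect_low: -7.067525023282535
      strong_down: -33.07972800759946
      strong_up: 46.83496702415179
    points:
      mild_down: 1
      mild_up: 1
      no_effect: 0
      strong_down: 3
      strong_up: 3
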
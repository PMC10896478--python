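# Neuropsychological test catalogue: domain assignment and score direction.
# higher_is_better: false marks timed tests (trail making, Stroop times)
# whose raw scores increase with worse performance; they are sign-flipped
# after z-scoring so every composite reads "higher = better".
tests:
  avlt_delayed_recall:        {domain: episodic_memory, higher_is_better: true}
  rocf_delayed_recall:        {domain: episodic_memory, higher_is_better: true}
  logical_memory_delayed:     {domain: episodic_memory, higher_is_better: true}
  clock_drawing:              {domain: visuospatial, higher_is_better: true}
  rocf_copy:                  {domain: visuospatial, higher_is_better: true}
  digit_span:                 {domain: executive, higher_is_better: true}
  trail_making_b_time:        {domain: executive, higher_is_better: false}
  verbal_fluency:             {domain: executive, higher_is_better: true}
  stroop_c_time:              {domain: executive, higher_is_better: false}
  semantic_similarity:        {domain: executive, higher_is_better: true}
  symbol_digit_modalities:    {domain: information_processing_speed, higher_is_better: true}
  trail_making_a_time:        {domain: information_processing_speed, higher_is_better: false}
  stroop_a_time:              {domain: information_processing_speed, higher_is_better: false}
  stroop_b_time:              {domain: information_processing_speed, higher_is_better: false}
  mmse:                       {domain: global, higher_is_better: true}
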
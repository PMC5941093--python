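# SYNTHETIC ASQ domain cutoffs (default age version).
#
# Real ASQ-3 cutoffs are age-normed proprietary values; these synthetic
# stand-ins preserve the structure the scorer needs: per domain a "refer"
# cutoff (score equivalent of -2 SD; sum below it => refer) and a "monitor"
# cutoff (-1 SD; refer_cutoff <= sum < monitor_cutoff => monitor).
# Domain sums range 0..60 (6 items scored 0/5/10).
cutoffs:
  gross_motor:      {refer: 25.0, monitor: 40.0}
  fine_motor:       {refer: 25.0, monitor: 40.0}
  personal_social:  {refer: 25.0, monitor: 40.0}
  problem_solving:  {refer: 25.0, monitor: 40.0}
  communication:    {refer: 25.0, monitor: 40.0}
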
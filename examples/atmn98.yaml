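# Restrict the grid search to daily minimum apparent temperature at the
# 98th-percentile threshold (the truth cell of the packaged E1 example).
grid:
  metrics: [ATMN]
  percentiles: [98]
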
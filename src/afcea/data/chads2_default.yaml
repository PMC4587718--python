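# Default stroke-risk stratification grid: annual ischemic stroke rate on
# aspirin by CHADS2 score.  These are externally sourced literature values
# (adjusted stroke rates from the National Registry of Atrial Fibrillation
# validation of the CHADS2 index) supplied as a convenience default; they
# are configuration inputs, not model constants, and can be replaced freely.
chads2_stroke_rates:
  "0": 0.019
  "1": 0.028
  "2": 0.040
  "3": 0.059
  "4": 0.085
  "5": 0.125
  "6": 0.182
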
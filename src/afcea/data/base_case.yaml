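# Base-case model inputs: annual event probabilities, relative risks,
# fatality fractions, 2005-USD costs, and utility weights for the
# aspirin-vs-genetic-test adherence comparison in atrial fibrillation.
# Probabilities may be written as fractions or percent strings ("4.5%").

# annual event probabilities and relative risks
p_stroke_aspirin: 0.045        # ischemic stroke on aspirin, per year
rr_stroke_warfarin: 0.48       # stroke relative risk, warfarin vs aspirin
p_bleed_warfarin: 0.025        # major hemorrhage (incl. ICH) on warfarin, per year
rr_bleed_aspirin: 0.59         # hemorrhage relative risk, aspirin vs warfarin

# event-severity fractions
frac_ich: 0.2                  # share of major hemorrhages that are intracranial
frac_fatal_stroke_warfarin: 0.082
frac_fatal_stroke_aspirin: 0.179
frac_fatal_ich: 0.364
frac_fatal_bleed_excl_ich: 0.049

# costs (2005 USD)
cost_warfarin_annual: 180
cost_aspirin_annual: 10
cost_fatal_stroke_once: 12130
cost_stroke_once_warfarin: 9667
cost_stroke_monthly_warfarin: 2652
cost_stroke_once_aspirin: 9610
cost_stroke_monthly_aspirin: 2168
cost_ich_once: 31810
cost_ich_monthly: 4690
cost_bleed_excl_ich_once: 3620
cost_genetic_test: 100         # two-SNP genotyping, one-time per tested person

# utilities (QALY weights)
u_well_warfarin: 0.987
u_well_aspirin: 0.998
u_stroke_warfarin: 0.476
u_stroke_aspirin: 0.426
u_ich: 0.4
u_recurrent_stroke: 0.12
u_dead: 0.0

# structural constants
cohort_size: 1000
horizon_cycles: 5
discount_rate: 0.03
test_positive_fraction: 0.40   # >= 1 risk allele at rs2200733/rs10033464
p_convert_base: 0.025          # annual decliner-to-warfarin conversion
conv_mult_test_positive: 2.0
conv_mult_test_negative: 0.5
wtp_per_qaly: 50000

# sensitivity ranges: (low, high); grouped multipliers scale all drug/event
# costs (+-50%) or all non-fatal event-state utilities (+-20%) jointly
ranges:
  p_stroke_aspirin: [0.03, 0.06]
  rr_stroke_warfarin: [0.37, 0.63]
  p_bleed_warfarin: [0.02, 0.04]
  rr_bleed_aspirin: [0.50, 0.70]
  cost_genetic_test: [50, 200]
  cost_multiplier: [0.5, 1.5]
  utility_multiplier: [0.8, 1.2]
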
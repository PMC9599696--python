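"""Score single rule-based items by hand.

The rule layer compares a paretic-side feature with a reference (the
subject's less-affected side, or a cohort normal constant) and cuts the
performance ratio at 1/3 and 2/3 into the three score bands.
"""

from fmascore import load_rules, score_rb_item

rules = load_rules()

# item 26 (hook grasp): peak force 12 N vs 30 N on the other hand
score = score_rb_item(26, {"X:force_max": 12.0}, {"X:force_max": 30.0})
print(f"item 26, force ratio 12/30 = 0.40      -> score {score}")

# item 20 (repeated wrist flexion): full range on both sides
score = score_rb_item(20, {"VII90:wrist_pitch_max": 25.0,
                           "VII90:wrist_pitch_rom": 54.0},
                      {"VII90:wrist_pitch_max": 25.0,
                       "VII90:wrist_pitch_rom": 55.0})
print(f"item 20, ROM ratio 54/55 = 0.98        -> score {score}")

# item 33 (finger-to-nose time): fast enough, but the wrist never came
# within reach of the nose, so the prerequisite forces a zero
score = score_rb_item(33, {"XV:movement_time": 1.4,
                           "XV:nose_distance_min": 0.38},
                      {"XV:movement_time": 1.5,
                       "XV:nose_distance_min": 0.08})
print(f"item 33, prerequisite not met          -> score {score}")
# Ratios below 1/3 score 0, between 1/3 and 2/3 score 1, above 2/3
# score 2; unmet prerequisites short-circuit to 0.
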
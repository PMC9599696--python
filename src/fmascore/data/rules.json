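{
  "comment": "Rule bindings for the 17 rule-based items. Each sub-rule compares a paretic-side feature against a reference: 'h' = the same subject's less-affected side, 'N' = the cohort normal constant (mean of all subjects' less-affected values). Items with several sub-rules take the minimum. Bindings were reconstructed from each item's published feature list and are shipped as data so clinicians can audit or adjust them.",
  "items": [
    {
      "item_id": 14,
      "prerequisite": {"kind": "reach_initial_position",
                       "feature": "VI90:elbow_flexion_max"},
      "rules": [{"feature": "VI90:forearm_rotation_max",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "pronation/supination amplitude once the elbow-90 start position is reached"
    },
    {
      "item_id": 17,
      "prerequisite": {"kind": "reach_initial_position",
                       "feature": "VI0:shoulder_flexion_max"},
      "rules": [{"feature": "VI0:forearm_rotation_max",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "pronation/supination amplitude once the extended-arm start position is reached"
    },
    {
      "item_id": 19,
      "rules": [{"feature": "VII90:wrist_pitch_max",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "attained dorsiflexion angle (stability at 15 deg)"
    },
    {
      "item_id": 20,
      "rules": [{"feature": "VII90:wrist_pitch_rom",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "dorsi/volar flexion excursion over repeated cycles"
    },
    {
      "item_id": 21,
      "rules": [{"feature": "VII0:wrist_pitch_max",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "attained dorsiflexion angle with the elbow extended"
    },
    {
      "item_id": 22,
      "rules": [{"feature": "VII0:wrist_pitch_rom",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "dorsi/volar flexion excursion with the elbow extended"
    },
    {
      "item_id": 23,
      "rules": [{"feature": "VIII:wrist_pitch_rom",
                 "reference": "h", "direction": "higher_better"},
                {"feature": "VIII:wrist_yaw_rom",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "circumduction needs excursion in both wrist planes; minimum of the two sub-rules"
    },
    {
      "item_id": 24,
      "finger_model": true,
      "finger_feature_template": "IX:finger{i}_flexion_max",
      "reference": "h",
      "direction": "higher_better",
      "basis": "per-finger flexion peak scored 0/1/2; item score from the 4-finger total out of 8"
    },
    {
      "item_id": 25,
      "finger_model": true,
      "finger_feature_template": "IX:finger{i}_extension_range",
      "reference": "h",
      "direction": "higher_better",
      "basis": "per-finger active extension excursion from full flexion"
    },
    {
      "item_id": 26,
      "rules": [{"feature": "X:force_max",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "peak grip force on the hook tool"
    },
    {
      "item_id": 27,
      "rules": [{"feature": "XI:force_max",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "peak grip force on the thumb-adduction tool"
    },
    {
      "item_id": 28,
      "rules": [{"feature": "XII:force_max",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "peak grip force on the pincer tool"
    },
    {
      "item_id": 29,
      "rules": [{"feature": "XIII:force_max",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "peak grip force on the cylinder tool"
    },
    {
      "item_id": 30,
      "rules": [{"feature": "XIV:force_max",
                 "reference": "h", "direction": "higher_better"}],
      "basis": "peak grip force on the sphere tool"
    },
    {
      "item_id": 31,
      "rules": [{"feature": "XV:sparc_magnitude",
                 "reference": "N", "direction": "lower_better"}],
      "basis": "tremor roughens the wrist speed profile, inflating |SPARC|; smaller magnitude is smoother"
    },
    {
      "item_id": 32,
      "rules": [{"feature": "XV:nose_distance_min",
                 "reference": "N", "direction": "lower_better"}],
      "basis": "dysmetria leaves a residual wrist-nose distance at the end of the pointing movement"
    },
    {
      "item_id": 33,
      "prerequisite": {"kind": "point_to_nose",
                       "feature": "XV:nose_distance_min"},
      "rules": [{"feature": "XV:movement_time",
                 "reference": "h", "direction": "lower_better"}],
      "basis": "movement time relative to the less-affected side, provided the nose is actually reached"
    }
  ]
}
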
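{
  "dyads": [
    {"id": 1, "name_pair": ["Anger", "Rage"], "wheel_position": 6},
    {"id": 2, "name_pair": ["Engagement", "Anticipation"], "wheel_position": 7},
    {"id": 3, "name_pair": ["Disgust", "Disconnection"], "wheel_position": 5},
    {"id": 4, "name_pair": ["Fear", "Worry"], "wheel_position": 2},
    {"id": 5, "name_pair": ["Joy", "Affection"], "wheel_position": 0},
    {"id": 6, "name_pair": ["Sadness", "Discouragement"], "wheel_position": 4},
    {"id": 7, "name_pair": ["Surprise", "Amazement"], "wheel_position": 3},
    {"id": 8, "name_pair": ["Trust", "Peace"], "wheel_position": 1}
  ],
  "emotic_map": {
    "Anger": 1,
    "Annoyance": 1,
    "Disapproval": 1,
    "Anticipation": 2,
    "Engagement": 2,
    "Aversion": 3,
    "Disconnection": 3,
    "Fatigue": 3,
    "Yearning": 3,
    "Disquitement": 4,
    "Embarrassment": 4,
    "Fear": 4,
    "Affection": 5,
    "Excitement": 5,
    "Happiness": 5,
    "Pleasure": 5,
    "Pain": 6,
    "Sadness": 6,
    "Sensitivity": 6,
    "Suffering": 6,
    "Doubt/Confussion": 7,
    "Suprise": 7,
    "Confidence": 8,
    "Esteem": 8,
    "Sympathy": 8,
    "Peace": 8
  },
  "aliases": {
    "Disquietment": "Disquitement",
    "Doubt/Confusion": "Doubt/Confussion",
    "Surprise": "Suprise"
  }
}
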
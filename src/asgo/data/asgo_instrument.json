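{
  "name": "ASGO",
  "version": "1.0",
  "description": "General Assessment of Hospitalised Patient: 10 non-medical functions weighted by commitment to support needs. The raw score is the sum of selected ranking values (ranking value = variable weight x modality level); the functional-dependence index is raw score / 10.",
  "variables": [
    {
      "name": "mental_status",
      "weight": 1.6,
      "multi_select": false,
      "modalities": [
        {"level": 1, "label": "awake and lucid", "ranking_value": 1.6},
        {"level": 2, "label": "non-responsive", "ranking_value": 3.2},
        {"level": 3, "label": "comatose", "ranking_value": 4.8},
        {"level": 4, "label": "disoriented behaviour", "ranking_value": 6.4},
        {"level": 5, "label": "slowed thinking", "ranking_value": 8.0},
        {"level": 6, "label": "memory loss", "ranking_value": 9.6},
        {"level": 7, "label": "forgetfulness and confusion", "ranking_value": 11.2}
      ]
    },
    {
      "name": "movement_ambulation",
      "weight": 1.3,
      "multi_select": false,
      "modalities": [
        {"level": 1, "label": "full movement", "ranking_value": 1.3},
        {"level": 2, "label": "walking aids", "ranking_value": 2.6},
        {"level": 3, "label": "autonomous wheelchair user", "ranking_value": 3.9},
        {"level": 4, "label": "bedridden", "ranking_value": 5.2},
        {"level": 5, "label": "bedridden with risk of falling", "ranking_value": 6.5},
        {"level": 7, "label": "supported by someone", "ranking_value": 9.1}
      ]
    },
    {
      "name": "circulation",
      "weight": 0.4,
      "multi_select": true,
      "modalities": [
        {"level": 1, "label": "adequate", "ranking_value": 0.4},
        {"level": 2, "label": "oedemas", "ranking_value": 0.8},
        {"level": 3, "label": "cold", "ranking_value": 1.2},
        {"level": 4, "label": "hypotension", "ranking_value": 1.6},
        {"level": 5, "label": "fatigue", "ranking_value": 2.0},
        {"level": 6, "label": "erythema", "ranking_value": 2.4},
        {"level": 7, "label": "skin ulcers", "ranking_value": 2.8}
      ]
    },
    {
      "name": "breathing",
      "weight": 0.4,
      "multi_select": false,
      "modalities": [
        {"level": 1, "label": "adequate", "ranking_value": 0.4},
        {"level": 2, "label": "tracheostomy", "ranking_value": 0.8},
        {"level": 3, "label": "mechanical ventilation", "ranking_value": 1.2},
        {"level": 4, "label": "body position required", "ranking_value": 1.6},
        {"level": 5, "label": "self-management of respiratory therapy", "ranking_value": 2.0},
        {"level": 6, "label": "fatigue", "ranking_value": 2.4},
        {"level": 7, "label": "impaired, with O2 support", "ranking_value": 2.8}
      ]
    },
    {
      "name": "elimination_sphincters",
      "weight": 1.2,
      "multi_select": true,
      "modalities": [
        {"level": 1, "label": "normal", "ranking_value": 1.2},
        {"level": 2, "label": "urinary catheter", "ranking_value": 2.4},
        {"level": 3, "label": "faecal incontinence", "ranking_value": 3.6},
        {"level": 4, "label": "urinary incontinence", "ranking_value": 4.8},
        {"level": 5, "label": "partial urinary control", "ranking_value": 6.0},
        {"level": 6, "label": "faecal partial control", "ranking_value": 7.2},
        {"level": 7, "label": "enterostomy", "ranking_value": 8.4}
      ]
    },
    {
      "name": "feeding",
      "weight": 0.6,
      "multi_select": true,
      "modalities": [
        {"level": 1, "label": "free", "ranking_value": 0.6},
        {"level": 2, "label": "enteral nutrition", "ranking_value": 1.2},
        {"level": 3, "label": "parenteral nutrition", "ranking_value": 1.8},
        {"level": 4, "label": "mouth ulcers/infections", "ranking_value": 2.4},
        {"level": 5, "label": "difficult/painful swallowing", "ranking_value": 3.0},
        {"level": 6, "label": "limited/absent chewing", "ranking_value": 3.6},
        {"level": 7, "label": "spoon-fed/direct eating help", "ranking_value": 4.2}
      ]
    },
    {
      "name": "sleep_wake",
      "weight": 1.2,
      "multi_select": false,
      "modalities": [
        {"level": 1, "label": "regular", "ranking_value": 1.2},
        {"level": 2, "label": "sleep medicine", "ranking_value": 2.4},
        {"level": 3, "label": "regular bedtime routine", "ranking_value": 3.6},
        {"level": 4, "label": "tiredness", "ranking_value": 4.8},
        {"level": 5, "label": "frequent awakenings", "ranking_value": 6.0},
        {"level": 6, "label": "unrefreshing sleep", "ranking_value": 7.2},
        {"level": 7, "label": "disturbed sleep, apnoea", "ranking_value": 8.4}
      ]
    },
    {
      "name": "sensory_system",
      "weight": 0.6,
      "multi_select": true,
      "modalities": [
        {"level": 1, "label": "normal", "ranking_value": 0.6},
        {"level": 2, "label": "hearing impaired", "ranking_value": 1.2},
        {"level": 3, "label": "visually impaired", "ranking_value": 1.8},
        {"level": 4, "label": "deaf", "ranking_value": 2.4},
        {"level": 5, "label": "blind", "ranking_value": 3.0},
        {"level": 6, "label": "environmental perception impaired", "ranking_value": 3.6},
        {"level": 7, "label": "pain", "ranking_value": 4.2}
      ]
    },
    {
      "name": "self_care",
      "weight": 1.3,
      "multi_select": false,
      "modalities": [
        {"level": 1, "label": "complete", "ranking_value": 1.3},
        {"level": 2, "label": "minimal bathing assistance", "ranking_value": 2.6},
        {"level": 3, "label": "major bathing assistance", "ranking_value": 3.9},
        {"level": 4, "label": "unable to dress", "ranking_value": 5.2},
        {"level": 5, "label": "passive movement", "ranking_value": 6.5},
        {"level": 6, "label": "following movements", "ranking_value": 7.8},
        {"level": 7, "label": "basic moves", "ranking_value": 9.1}
      ]
    },
    {
      "name": "prevailing_mood",
      "weight": 1.4,
      "multi_select": false,
      "modalities": [
        {"level": 1, "label": "stable", "ranking_value": 1.4},
        {"level": 2, "label": "needs to be encouraged", "ranking_value": 2.8},
        {"level": 3, "label": "social withdrawal", "ranking_value": 4.2},
        {"level": 4, "label": "emotional stress", "ranking_value": 5.6},
        {"level": 5, "label": "anxiety", "ranking_value": 7.0},
        {"level": 6, "label": "apathy", "ranking_value": 8.4},
        {"level": 7, "label": "depression, suicidal ideation", "ranking_value": 9.8}
      ]
    }
  ],
  "profile_bands": [
    {"profile": "minimum", "lower": 1.0, "upper": 2.6},
    {"profile": "medium", "lower": 2.6, "upper": 3.7},
    {"profile": "high", "lower": 3.7, "upper": 4.8},
    {"profile": "maximum", "lower": 4.8, "upper": null}
  ]
}
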
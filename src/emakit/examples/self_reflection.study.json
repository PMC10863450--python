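{
  "schema_version": 1,
  "study_code": "REFLECT1",
  "title": "Three-day self-reflection pilot",
  "interventions": [
    {
      "id": "daily_reflection",
      "name": "Daily mood reflection",
      "assignment_policy": "auto_assign",
      "modules": [
        {
          "id": "m_welcome",
          "title": "Welcome and first check-in",
          "items": [
            {
              "id": "i_welcome_info",
              "item_type": "info_content",
              "prompt": "Welcome! Over the next days we will ask how you feel."
            },
            {
              "id": "i_mood_1",
              "item_type": "slider",
              "prompt": "How happy are you today? (1-10)",
              "variable": "mood_day1"
            }
          ],
          "opening_rules": [
            {"rule": "relative_to_intervention_start", "offset_minutes": 0}
          ],
          "closing_rules": [
            {"rule": "relative_to_module_start", "offset_minutes": 1440}
          ],
          "notifications": [
            {
              "kind": "opening",
              "text": "Your first check-in is ready.",
              "trigger": {"trigger": "interval_after_open", "offset_minutes": 0}
            },
            {
              "kind": "reminder",
              "text": "Don't forget today's check-in.",
              "reminder_offset_minutes": 60
            },
            {
              "kind": "closing",
              "text": "Your check-in closes soon."
            }
          ]
        },
        {
          "id": "m_day2",
          "title": "Second check-in",
          "items": [
            {
              "id": "i_mood_2",
              "item_type": "slider",
              "prompt": "How happy are you today? (1-10)",
              "variable": "mood_day2"
            },
            {
              "id": "i_reflect_2",
              "item_type": "open_text",
              "prompt": "What influenced your mood most today?",
              "variable": "reflection_day2"
            }
          ],
          "opening_rules": [
            {
              "rule": "relative_to_module_completion",
              "ref_module_id": "m_welcome",
              "offset_minutes": 1440
            }
          ],
          "closing_rules": [
            {"rule": "relative_to_module_start", "offset_minutes": 1440}
          ],
          "notifications": [
            {
              "kind": "reminder",
              "text": "Time for your second check-in.",
              "reminder_offset_minutes": 120
            }
          ]
        },
        {
          "id": "m_low_mood_support",
          "title": "Support exercises",
          "items": [
            {
              "id": "i_support_info",
              "item_type": "info_content",
              "prompt": "A short breathing exercise can help on harder days."
            },
            {
              "id": "i_support_helpful",
              "item_type": "closed",
              "prompt": "Was this exercise helpful?",
              "variable": "support_helpful",
              "options": [
                {"label": "yes", "code": 1},
                {"label": "no", "code": 0}
              ]
            }
          ],
          "opening_rules": [
            {
              "rule": "answer_condition",
              "ref_item_id": "i_mood_2",
              "comparator": "le",
              "value": 4
            },
            {
              "rule": "on_module_not_finished",
              "ref_module_id": "m_day2",
              "check_offset_minutes": 2880
            }
          ],
          "closing_rules": [
            {"rule": "relative_to_module_start", "offset_minutes": 2880}
          ],
          "notifications": [
            {
              "kind": "closing",
              "text": "The support module closes soon."
            }
          ]
        }
      ],
      "calc_variables": [
        {"name": "mood_2day_avg", "expression": "(mood_day1 + mood_day2) / 2"},
        {"name": "cohort_mood_mode", "expression": "MODE_ANS(mood_day1)"},
        {"name": "cohort_response_rate",
         "expression": "NUM_P_ANS(mood_day1) / NUM_PS(mood_day1)"}
      ]
    }
  ]
}
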
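{
  "criteria": [
    {
      "id": "guidelines",
      "label": "Guidelines",
      "subcriteria": [
        {
          "id": "guid_adult",
          "label": "Adult"
        },
        {
          "id": "guid_pediatric",
          "label": "Pediatric"
        },
        {
          "id": "guid_senior",
          "label": "Senior"
        },
        {
          "id": "guid_pregnant",
          "label": "Pregnant"
        },
        {
          "id": "guid_disabled",
          "label": "Disabled"
        },
        {
          "id": "guid_aggressive",
          "label": "Aggressive"
        },
        {
          "id": "guid_alcoholics",
          "label": "Alcoholics"
        },
        {
          "id": "guid_nurses_simple_cases",
          "label": "Nurses Attendance in Simple Cases"
        }
      ]
    },
    {
      "id": "ease_of_evaluation",
      "label": "Ease of Evaluation",
      "subcriteria": [
        {
          "id": "eval_medical_history",
          "label": "Medical History"
        },
        {
          "id": "eval_pain_scale",
          "label": "Pain Scale"
        },
        {
          "id": "eval_use_of_medications",
          "label": "Use of Medications"
        },
        {
          "id": "eval_allergies",
          "label": "Allergies"
        },
        {
          "id": "eval_physical_evaluation",
          "label": "Physical Evaluation"
        },
        {
          "id": "eval_mental_evaluation",
          "label": "Mental Evaluation"
        },
        {
          "id": "eval_vital_signs",
          "label": "Vital Signs"
        },
        {
          "id": "eval_re_triage",
          "label": "Re-triage"
        }
      ]
    },
    {
      "id": "ease_of_use",
      "label": "Ease of Use",
      "subcriteria": [
        {
          "id": "use_color_scale",
          "label": "Use of Color Scale"
        },
        {
          "id": "use_max_waiting_time",
          "label": "Maximum Waiting Time"
        },
        {
          "id": "use_max_triage_time",
          "label": "Maximum Triage Time"
        },
        {
          "id": "use_max_service_time",
          "label": "Maximum Service Time"
        },
        {
          "id": "use_total_triage",
          "label": "Total Triage (5 levels)"
        },
        {
          "id": "use_partial_triage",
          "label": "Partial Triage (2 + 3 levels)"
        },
        {
          "id": "use_nurses_simple_cases",
          "label": "Nurses Attendance in Simple Cases"
        },
        {
          "id": "use_computer_software",
          "label": "Use of Computer and Software"
        }
      ]
    },
    {
      "id": "ease_of_implementation",
      "label": "Ease of Implementation",
      "subcriteria": [
        {
          "id": "impl_training",
          "label": "Training of employees"
        },
        {
          "id": "impl_need_computer",
          "label": "Need for computer"
        },
        {
          "id": "impl_specific_software",
          "label": "Use of specific software"
        }
      ]
    }
  ]
}
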
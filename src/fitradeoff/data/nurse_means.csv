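subcriterion,mean
guid_adult,4.90
guid_pediatric,4.10
guid_senior,4.65
guid_pregnant,3.60
guid_disabled,3.95
guid_aggressive,3.75
guid_alcoholics,3.75
guid_nurses_simple_cases,3.45
eval_medical_history,4.90
eval_pain_scale,4.55
eval_use_of_medications,4.55
eval_allergies,4.95
eval_physical_evaluation,4.40
eval_mental_evaluation,4.40
eval_vital_signs,4.95
eval_re_triage,4.65
use_color_scale,4.65
use_max_waiting_time,3.75
use_max_triage_time,3.90
use_max_service_time,4.30
use_total_triage,2.60
use_partial_triage,4.40
use_nurses_simple_cases,4.00
use_computer_software,4.60
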
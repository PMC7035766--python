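alternative,subcriterion,coverage
ATS,guid_adult,1
CTAS,guid_adult,1
MTS,guid_adult,1
ESI,guid_adult,1
SET,guid_adult,1
ATS,guid_pediatric,1
CTAS,guid_pediatric,1
MTS,guid_pediatric,0.5
ESI,guid_pediatric,1
SET,guid_pediatric,0
ATS,guid_senior,1
CTAS,guid_senior,0
MTS,guid_senior,0.5
ESI,guid_senior,0
SET,guid_senior,0
ATS,guid_pregnant,1
CTAS,guid_pregnant,0.5
MTS,guid_pregnant,0
ESI,guid_pregnant,1
SET,guid_pregnant,0
ATS,guid_disabled,0
CTAS,guid_disabled,0.5
MTS,guid_disabled,0.5
ESI,guid_disabled,0
SET,guid_disabled,0
ATS,guid_aggressive,1
CTAS,guid_aggressive,0
MTS,guid_aggressive,0.5
ESI,guid_aggressive,0
SET,guid_aggressive,0
ATS,guid_alcoholics,0
CTAS,guid_alcoholics,0
MTS,guid_alcoholics,0.5
ESI,guid_alcoholics,0
SET,guid_alcoholics,0
ATS,guid_nurses_simple_cases,0
CTAS,guid_nurses_simple_cases,0
MTS,guid_nurses_simple_cases,0
ESI,guid_nurses_simple_cases,0
SET,guid_nurses_simple_cases,1
ATS,eval_medical_history,1
CTAS,eval_medical_history,1
MTS,eval_medical_history,1
ESI,eval_medical_history,1
SET,eval_medical_history,1
ATS,eval_pain_scale,1
CTAS,eval_pain_scale,1
MTS,eval_pain_scale,1
ESI,eval_pain_scale,0
SET,eval_pain_scale,1
ATS,eval_use_of_medications,0
CTAS,eval_use_of_medications,1
MTS,eval_use_of_medications,0
ESI,eval_use_of_medications,0
SET,eval_use_of_medications,0
ATS,eval_allergies,0
CTAS,eval_allergies,1
MTS,eval_allergies,0
ESI,eval_allergies,0
SET,eval_allergies,0
ATS,eval_physical_evaluation,1
CTAS,eval_physical_evaluation,1
MTS,eval_physical_evaluation,0
ESI,eval_physical_evaluation,0
SET,eval_physical_evaluation,0
ATS,eval_mental_evaluation,1
CTAS,eval_mental_evaluation,0
MTS,eval_mental_evaluation,0
ESI,eval_mental_evaluation,0
SET,eval_mental_evaluation,0
ATS,eval_vital_signs,0.5
CTAS,eval_vital_signs,0
MTS,eval_vital_signs,0
ESI,eval_vital_signs,0
SET,eval_vital_signs,1
ATS,eval_re_triage,1
CTAS,eval_re_triage,1
MTS,eval_re_triage,0
ESI,eval_re_triage,0
SET,eval_re_triage,0
ATS,use_color_scale,1
CTAS,use_color_scale,1
MTS,use_color_scale,1
ESI,use_color_scale,1
SET,use_color_scale,1
ATS,use_max_waiting_time,1
CTAS,use_max_waiting_time,1
MTS,use_max_waiting_time,0
ESI,use_max_waiting_time,0
SET,use_max_waiting_time,0
ATS,use_max_triage_time,1
CTAS,use_max_triage_time,1
MTS,use_max_triage_time,0
ESI,use_max_triage_time,0
SET,use_max_triage_time,0
ATS,use_max_service_time,1
CTAS,use_max_service_time,1
MTS,use_max_service_time,1
ESI,use_max_service_time,0
SET,use_max_service_time,1
ATS,use_total_triage,1
CTAS,use_total_triage,0
MTS,use_total_triage,1
ESI,use_total_triage,0
SET,use_total_triage,1
ATS,use_partial_triage,0
CTAS,use_partial_triage,1
MTS,use_partial_triage,0
ESI,use_partial_triage,1
SET,use_partial_triage,0
ATS,use_nurses_simple_cases,0
CTAS,use_nurses_simple_cases,0
MTS,use_nurses_simple_cases,0
ESI,use_nurses_simple_cases,0
SET,use_nurses_simple_cases,1
ATS,use_computer_software,0
CTAS,use_computer_software,0.5
MTS,use_computer_software,1
ESI,use_computer_software,0
SET,use_computer_software,1
ATS,impl_training,1
CTAS,impl_training,1
MTS,impl_training,1
ESI,impl_training,1
SET,impl_training,1
ATS,impl_need_computer,0
CTAS,impl_need_computer,1
MTS,impl_need_computer,1
ESI,impl_need_computer,0
SET,impl_need_computer,1
ATS,impl_specific_software,0
CTAS,impl_specific_software,0
MTS,impl_specific_software,1
ESI,impl_specific_software,0
SET,impl_specific_software,1
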
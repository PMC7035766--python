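alternative,subcriterion,score
ATS,guid_adult,5
CTAS,guid_adult,5
MTS,guid_adult,5
ESI,guid_adult,5
SET,guid_adult,5
ATS,guid_pediatric,5
CTAS,guid_pediatric,5
MTS,guid_pediatric,1
ESI,guid_pediatric,5
SET,guid_pediatric,0
ATS,guid_senior,5
CTAS,guid_senior,0
MTS,guid_senior,1
ESI,guid_senior,0
SET,guid_senior,0
ATS,guid_pregnant,5
CTAS,guid_pregnant,3
MTS,guid_pregnant,0
ESI,guid_pregnant,5
SET,guid_pregnant,0
ATS,guid_disabled,0
CTAS,guid_disabled,2
MTS,guid_disabled,2
ESI,guid_disabled,0
SET,guid_disabled,0
ATS,guid_aggressive,5
CTAS,guid_aggressive,0
MTS,guid_aggressive,2
ESI,guid_aggressive,0
SET,guid_aggressive,0
ATS,guid_alcoholics,0
CTAS,guid_alcoholics,0
MTS,guid_alcoholics,2
ESI,guid_alcoholics,0
SET,guid_alcoholics,0
ATS,guid_nurses_simple_cases,0
CTAS,guid_nurses_simple_cases,0
MTS,guid_nurses_simple_cases,0
ESI,guid_nurses_simple_cases,0
SET,guid_nurses_simple_cases,5
ATS,eval_medical_history,5
CTAS,eval_medical_history,5
MTS,eval_medical_history,5
ESI,eval_medical_history,5
SET,eval_medical_history,5
ATS,eval_pain_scale,5
CTAS,eval_pain_scale,5
MTS,eval_pain_scale,5
ESI,eval_pain_scale,0
SET,eval_pain_scale,5
ATS,eval_use_of_medications,0
CTAS,eval_use_of_medications,5
MTS,eval_use_of_medications,0
ESI,eval_use_of_medications,0
SET,eval_use_of_medications,0
ATS,eval_allergies,0
CTAS,eval_allergies,5
MTS,eval_allergies,0
ESI,eval_allergies,0
SET,eval_allergies,0
ATS,eval_physical_evaluation,4
CTAS,eval_physical_evaluation,4
MTS,eval_physical_evaluation,0
ESI,eval_physical_evaluation,0
SET,eval_physical_evaluation,0
ATS,eval_mental_evaluation,4
CTAS,eval_mental_evaluation,0
MTS,eval_mental_evaluation,0
ESI,eval_mental_evaluation,0
SET,eval_mental_evaluation,0
ATS,eval_vital_signs,1
CTAS,eval_vital_signs,0
MTS,eval_vital_signs,0
ESI,eval_vital_signs,0
SET,eval_vital_signs,5
ATS,eval_re_triage,5
CTAS,eval_re_triage,5
MTS,eval_re_triage,0
ESI,eval_re_triage,0
SET,eval_re_triage,0
ATS,use_color_scale,5
CTAS,use_color_scale,5
MTS,use_color_scale,5
ESI,use_color_scale,5
SET,use_color_scale,5
ATS,use_max_waiting_time,4
CTAS,use_max_waiting_time,4
MTS,use_max_waiting_time,0
ESI,use_max_waiting_time,0
SET,use_max_waiting_time,0
ATS,use_max_triage_time,0
CTAS,use_max_triage_time,0
MTS,use_max_triage_time,4
ESI,use_max_triage_time,4
SET,use_max_triage_time,4
ATS,use_max_service_time,5
CTAS,use_max_service_time,5
MTS,use_max_service_time,5
ESI,use_max_service_time,0
SET,use_max_service_time,5
ATS,use_total_triage,3
CTAS,use_total_triage,0
MTS,use_total_triage,3
ESI,use_total_triage,0
SET,use_total_triage,3
ATS,use_partial_triage,0
CTAS,use_partial_triage,4
MTS,use_partial_triage,0
ESI,use_partial_triage,4
SET,use_partial_triage,0
ATS,use_nurses_simple_cases,0
CTAS,use_nurses_simple_cases,0
MTS,use_nurses_simple_cases,0
ESI,use_nurses_simple_cases,0
SET,use_nurses_simple_cases,4
ATS,use_computer_software,0
CTAS,use_computer_software,2
MTS,use_computer_software,5
ESI,use_computer_software,0
SET,use_computer_software,5
ATS,impl_training,5
CTAS,impl_training,5
MTS,impl_training,5
ESI,impl_training,5
SET,impl_training,5
ATS,impl_need_computer,0
CTAS,impl_need_computer,3
MTS,impl_need_computer,3
ESI,impl_need_computer,0
SET,impl_need_computer,3
ATS,impl_specific_software,0
CTAS,impl_specific_software,0
MTS,impl_specific_software,4
ESI,impl_specific_software,0
SET,impl_specific_software,4
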
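name,design_type,mean,sd,family,unit,basis
protocol_development,two_group,123333,23245,lognormal,USD2021,per_trial
protocol_development,multigroup,136667,22480,lognormal,USD2021,per_trial
protocol_development,platform,155667,34347,lognormal,USD2021,per_trial
trial_approvals,two_group,151183,28126,lognormal,USD2021,per_trial
trial_approvals,multigroup,165367,27200,lognormal,USD2021,per_trial
trial_approvals,platform,172250,38538,lognormal,USD2021,per_trial
database_development,two_group,32500,30406,lognormal,USD2021,per_trial
database_development,multigroup,36667,34763,lognormal,USD2021,per_trial
database_development,platform,42500,30625,lognormal,USD2021,per_trial
site_setup,shared,9440,14086,lognormal,USD2021,per_site
protocol_development_time,two_group,3.92,1.98,normal,months,per_trial
protocol_development_time,multigroup,5.09,2.26,normal,months,per_trial
protocol_development_time,platform,8.78,3.83,normal,months,per_trial
trial_approvals_time,two_group,3.67,2.06,normal,months,per_trial
trial_approvals_time,multigroup,4.00,2.40,normal,months,per_trial
trial_approvals_time,platform,6.50,4.14,normal,months,per_trial
database_development_time,two_group,2.80,1.30,normal,months,per_trial
database_development_time,multigroup,3.20,1.30,normal,months,per_trial
database_development_time,platform,5.40,1.95,normal,months,per_trial
recruitment_per_patient,shared,1300,476,lognormal,USD2021,per_patient
monthly_followup_per_patient,shared,313,132,lognormal,USD2021,per_patient_month
site_management_per_site_month,shared,5000,3162,lognormal,USD2021,per_site_month
database_management_per_month,shared,2500,1061,lognormal,USD2021,per_trial_month
interim_analysis_per_group,shared,12883,29417,lognormal,USD2021,per_group_analysis
final_analysis_per_group,shared,42750,37053,lognormal,USD2021,per_group_analysis
add_group_cost,platform,75626,43528,lognormal,USD2021,per_added_group
add_group_time,platform,3.00,1.73,normal,months,per_added_group
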
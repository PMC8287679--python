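# Base-case parameters: NAC vs AC for cT2-4N0-1 NSCLC.
# Flat namespaced keys; any subset may be overridden in a user config.
# Probabilities: three-way postoperative outcome (sums to 1 per arm) and
# whole-course grade >=3 chemotherapy AE probability.
nac.p_no_complication: 0.82
nac.p_complication_ge3: 0.14
nac.p_postop_death: 0.04
nac.p_ae_ge3: 0.15
nac.p_receive_surgery: 1.0
nac.p_receive_chemo: 1.0
ac.p_no_complication: 0.91
ac.p_complication_ge3: 0.07
ac.p_postop_death: 0.02
ac.p_ae_ge3: 0.38
ac.p_receive_surgery: 1.0
ac.p_receive_chemo: 1.0
# Costs, 2020 RMB.
nac.surgery_base: 2351.96
nac.surgery_additional: 1854.46
nac.hosp_with_complication: 96462.0
nac.hosp_without_complication: 66800.0
nac.chemo_full_course: 30946.5
nac.imaging: 6036.0
nac.ae_treatment: 3679.8
ac.surgery_base: 2367.82
ac.surgery_additional: 2513.65
ac.hosp_with_complication: 96462.0
ac.hosp_without_complication: 66800.0
ac.chemo_full_course: 30946.5
ac.imaging: 3568.0
ac.ae_treatment: 3679.8
# Utility weights [0,1] and time frames (months).
utilities.u_surgery_chemo: 0.81
utilities.t_surgery_chemo: 4.87
utilities.u_ae: 0.45
utilities.t_ae: 0.73
utilities.u_complication: 0.63
utilities.t_complication: 0.5
utilities.u_surgery_alone: 0.77
utilities.t_surgery_alone: 0.53
utilities.u_chemo_alone: 1.0
utilities.t_chemo_alone: 0.21
utilities.u_post_treatment: 1.0
utilities.u_death: 0.0
# Horizon and decision settings.
os_nac_years: 9.1
os_ac_years: 9.1
wtp_threshold: 35446.0
cohort_size_source: 92
discount_rate: 0.0
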
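# Base-case parameter values for the shunt-surgery cost-utility model.
# Annual costs in euros; probabilities per cycle (year).
p_improved_y1: 0.73
p_complication_y1: 0.15
p_deteriorated_y1: 0.10
p_complication: 0.02
p_improved_after_complication: 0.70
p_deteriorated: 0.10
excess_mort_deteriorated: 0.10
mort_multiplier: 2.5
p_residential_shunt: 0.07
p_homeservice_shunt: 0.23
p_informal_shunt: 0.60
p_residential_nh: 0.42
p_daycare_nh: 0.06
c_surgery: 10200.0
c_inpatient: 3900.0
c_outpatient: 1700.0
c_residential: 60600.0
c_homeservice_shunt: 5200.0
c_homeservice_nh: 6900.0
c_daycare_nh: 9900.0
c_informal_shunt: 6600.0
c_informal_nh: 10500.0
u_improved: 0.71
u_poor: 0.57
discount_rate: 0.03
cohort_size: 1000
start_age: 70
max_age: 105
wtp_lower: 22150.0
wtp_upper: 33220.0
rate_homehelp_hour: 38.0
rate_informal_hour: 15.0
leisure_fraction: 0.35
hours_homecare_nh_daily: 0.5
hours_informal_nh_daily: 1.9
half_cycle_correction: true
excess_mode: additive
sd_rule: ci95
age_adjust_utilities: false
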
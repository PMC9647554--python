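id,value,provenance,source
age_weight.older,0.35,placeholder,assumed: Japanese adult age structure
age_weight.younger,0.65,placeholder,assumed: Japanese adult age structure
baseline_annual_risk.fall.older,0.2,placeholder,"assumed: NILS-LSA faller proportion, older adults"
baseline_annual_risk.fall.younger,0.1,placeholder,"assumed: NILS-LSA faller proportion, younger adults"
baseline_annual_risk.mvc.older,0.008,placeholder,assumed: Japanese collision statistics per driver
baseline_annual_risk.mvc.younger,0.01,placeholder,assumed: Japanese collision statistics per driver
baseline_annual_risk.wpa.younger,0.005,placeholder,assumed: MHLW occupational-accident survey
cost.fall_admit_hip_fracture,1200000,placeholder,assumed: NHI admission incl. hip surgery
cost.fall_admit_nonfracture,300000,placeholder,"assumed: NHI admission, non-fracture"
cost.fall_admit_nonhip_fracture,500000,placeholder,"assumed: NHI admission, non-hip fracture"
cost.fall_outpatient,20000,placeholder,assumed: NHI outpatient episode
cost.mvc,300000,placeholder,"assumed: general insurance data, medical cost per collision"
cost.wpa,200000,placeholder,"assumed: general insurance data, medical cost per accident"
disutility.fall,0.07,placeholder,assumed: US Medicare falls model order of magnitude
disutility.fracture_hip,0.1,placeholder,assumed: US Medicare falls model order of magnitude
disutility.fracture_nonhip,0.05,placeholder,assumed: US Medicare falls model order of magnitude
disutility.mvc,0.03,placeholder,assumed: weighted median utility loss per collision
disutility.wpa,0.0,printed,set to zero: no data identified
drug_cost_per_day.lemborexant,92.0,printed,2020 NHI drug tariff
drug_cost_per_day.suvorexant,96.7,printed,2020 NHI drug tariff
drug_cost_per_day.untreated,0.0,printed,untreated insomnia: no prescription
drug_cost_per_day.zolpidem_ir,28.4,printed,"2020 NHI drug tariff, brand/generic market-share weighted"
employment_ratio_older,0.243,printed,"employment rate at age >=65, statistics bureau"
fall_care.admit_nonfracture_frac,0.32,printed,US Medicare falls model: non-fracture admissions
fall_care.fracture_hip_frac,0.53,printed,US Medicare falls model: hip share of fracture admissions
fall_care.p_admit,0.08,printed,NILS-LSA: fallers hospitalized
fall_care.p_any_care,0.56,printed,NILS-LSA: fallers receiving medical care
fall_effect_vs_general.zolpidem_ir,2.5,placeholder,assumed: pooled analysis of zolpidem falls in older adults
fall_fatality.admit_hip_fracture,0.2,printed,US Medicare falls model: in-hospital fatality
fall_fatality.admit_nonfracture,0.06,printed,US Medicare falls model: in-hospital fatality
fall_fatality.admit_nonhip_fracture,0.001,printed,US Medicare falls model: in-hospital fatality
falls_per_faller_mean,2.5,printed,annual mean falls per faller used to weight the regression
horizon_years,0.5,printed,"model setting: 6-month horizon, no discounting"
hr_fall_vs_untreated.lemborexant,0.68,printed,"network meta-analysis, falls hazard ratio"
hr_fall_vs_untreated.suvorexant,0.85,printed,"network meta-analysis, falls hazard ratio"
insomnia_disutility.LPS,0.029,placeholder,assumed scenario input
insomnia_disutility.WASO,0.03,placeholder,assumed scenario input
insomnia_disutility.sSOL,0.026,printed,"SUNRISE 1 EQ-5D-3L ANCOVA, non-responders"
jpy_per_usd,107,printed,"Bank of Japan exchange rate, September 2020"
mvc_fatality,0.01,placeholder,"assumed: deaths per reported collision, Japan"
or_mvc.untreated,2.7,printed,"population-based case-control study, short sleep"
or_mvc.zolpidem,2.2,placeholder,assumed: US health-plan driving study; applied to all drugs
or_wpa_nonresponder,1.79,printed,"National Health Interview Survey, short sleepers"
owa_default_range_fraction,0.2,printed,model setting: +/-20% when no CI
psa_default_se_fraction,0.1,printed,model setting: assumed s.e. when unreported
psa_draws,2000,printed,model setting: Monte-Carlo simulation count
refall.anchor_falls,1.957,printed,2019 MCBS: annual falls per faller
refall.anchor_rate,0.25,placeholder,assumed: MCBS annual faller proportion
refall.slope,4.0,placeholder,assumed: precision-weighted regression slope (positive)
response_rate.LPS.lemborexant,0.4,placeholder,assumed scenario input
response_rate.LPS.suvorexant,0.4,placeholder,assumed scenario input
response_rate.LPS.untreated,0.0,printed,untreated insomnia: no improvement by definition
response_rate.LPS.zolpidem_ir,0.25,placeholder,assumed scenario input
response_rate.WASO.lemborexant,0.42,placeholder,assumed scenario input
response_rate.WASO.suvorexant,0.42,placeholder,assumed scenario input
response_rate.WASO.untreated,0.0,printed,untreated insomnia: no improvement by definition
response_rate.WASO.zolpidem_ir,0.3,placeholder,assumed scenario input
response_rate.sSOL.lemborexant,0.207,printed,SUNRISE 1 sSOL responder rate
response_rate.sSOL.suvorexant,0.207,printed,assumed equal to lemborexant (published assumption)
response_rate.sSOL.untreated,0.0,printed,untreated insomnia: no improvement by definition
response_rate.sSOL.zolpidem_ir,0.12,placeholder,assumed: below the orexin antagonists per network meta-analysis direction
rr_fall_untreated_vs_general,1.48,printed,"Study of Osteoporotic Fractures, untreated chronic insomnia"
utility_norm,0.86,placeholder,assumed: Japanese general-population EQ-5D norm
visit_cost_jpy,730,placeholder,assumed: NHI re-examination fee
visit_frequency_per_month,1.3,printed,"JMDC claims database, mean of 1.33 and 1.29"
wpa_fatality,0.002,placeholder,assumed: MHLW occupational fatality share
wtp_jpy_per_qaly,5000000,printed,Japanese HTA willingness-to-pay threshold
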
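# Model parameters for the VTE-prophylaxis decision-tree cost-effectiveness
# analysis. Sections mirror the row groups of the published probability table
# so the file can be diffed against it line by line. Probabilities are 30-day
# risks; costs are 2013 US$.

cohort_size: 10000

strategies:
  # p_dvt: 30-day incident DVT; p_bleed / p_hit: prophylaxis-associated
  # adverse events; prophylaxis_cost: 7-day course (0 for no prophylaxis).
  LMWH: {p_dvt: 0.055, p_bleed: 0.031, p_hit: 0.001, prophylaxis_cost: 380}
  UFH:  {p_dvt: 0.066, p_bleed: 0.058, p_hit: 0.010, prophylaxis_cost: 236}
  NONE: {p_dvt: 0.142, p_bleed: 0.020, p_hit: 0.000, prophylaxis_cost: 0}

consequences_of_aes:
  p_major_given_bleed: 0.185
  p_death_given_major_bleed: 0.148
  p_symptomatic_given_hit: 0.543
  p_death_given_symptomatic_hit: 0.098

dvt_treatment:
  p_bleed_given_dvt_tx: 0.083
  p_hit_given_dvt_tx: 0.012
  p_pe_given_dvt_tx: 0.018

pe_treatment:
  p_death_given_pe_tx_pos: 0.015   # fatality of treated PE
  p_death_given_pe_tx_neg: 0.003   # fatality of anticoagulation given no PE

natural_history:
  p_sudden_death_given_pe: 0.100
  p_pe_given_untreated_dvt: 0.511
  p_death_given_untreated_pe: 0.260
  p_death_underlying: 0.100        # 30-day mortality of the underlying illness

dvt_diagnosis:
  dvt_clin_sens: 0.657
  dvt_clin_spec: 0.869
  dvt_us_sens: 0.960
  dvt_us_spec: 0.962

pe_diagnosis:
  pe_clin_sens: 0.291
  pe_clin_spec: 0.910
  pe_ct_sens: 0.760
  pe_ct_spec: 0.894
  pe_vq_sens: 0.410
  pe_vq_spec: 0.970
  # arithmetic mean of the CT and V/Q rows; cross-checked at load
  pe_scan_avg_sens: 0.585
  pe_scan_avg_spec: 0.932

costs:
  major_bleed: 10717
  minor_bleed: 5466
  asymptomatic_hit: 1064
  symptomatic_hit: 14032
  treated_dvt: 10758
  treated_pe: 19032
  dvt_diagnosis: 449
  pe_diagnosis: 582

population:
  # US arm of the cross-sectional prophylaxis-practice survey
  endorse_counts:
    enrolled: 9257
    medical_ward: 5196
    at_vte_risk: 2720
    receiving_prophylaxis: 1292
    contraindicated: 331
  nis_eligible_total: 14300000     # annual eligible medical discharges
  at_risk_fraction: 0.511          # weighted share at ACCP-defined VTE risk
  at_risk_iqr: [0.448, 0.622]      # across-hospital IQR of that share
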
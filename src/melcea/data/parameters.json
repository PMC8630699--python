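{
  "survival": {
    "os_ipilimumab": {
      "family": "loglogistic",
      "params": [0.03916796, 1.52458],
      "time_unit": "months",
      "label": "Log-logistic OS survival model with ipilimumab (Theta, Kappa)"
    },
    "pfs_ipilimumab": {
      "family": "loglogistic",
      "params": [0.1380415, 1.922389],
      "time_unit": "months",
      "label": "Log-logistic PFS survival model with ipilimumab (Theta, Kappa)"
    }
  },
  "parameters": {
    "hr_os": {
      "baseline": 0.50, "min": 0.38, "max": 0.66, "distribution": "lognormal",
      "label": "HR of ipilimumab plus anti-PD-1 vs ipilimumab for OS"
    },
    "hr_pfs": {
      "baseline": 0.69, "min": 0.55, "max": 0.87, "distribution": "lognormal",
      "label": "HR of ipilimumab plus anti-PD-1 vs ipilimumab for PFS"
    },
    "response_share_combination": {
      "baseline": 0.31, "min": 0.25, "max": 0.37, "distribution": "beta",
      "label": "Percentage achieving treatment response, ipilimumab plus anti-PD-1 group"
    },
    "response_share_ipilimumab": {
      "baseline": 0.13, "min": 0.10, "max": 0.16, "distribution": "beta",
      "label": "Percentage achieving treatment response, ipilimumab group"
    },
    "u_response": {
      "baseline": 0.88, "min": 0.70, "max": 1.00, "distribution": "beta",
      "label": "Utility, complete/partial response"
    },
    "u_stable": {
      "baseline": 0.80, "min": 0.64, "max": 0.96, "distribution": "beta",
      "label": "Utility, stable disease"
    },
    "u_progressed": {
      "baseline": 0.52, "min": 0.42, "max": 0.62, "distribution": "beta",
      "label": "Utility, progressed disease"
    },
    "cost_ipilimumab_per_mg": {
      "baseline": 166, "min": 133, "max": 199, "distribution": "gamma",
      "label": "Ipilimumab cost per mg"
    },
    "cost_nivolumab_per_mg": {
      "baseline": 30, "min": 24, "max": 36, "distribution": "gamma",
      "label": "Nivolumab cost per mg"
    },
    "cost_pembrolizumab_per_mg": {
      "baseline": 55, "min": 44, "max": 66, "distribution": "gamma",
      "label": "Pembrolizumab cost per mg"
    },
    "cost_bsc": {
      "baseline": 4492, "min": 3594, "max": 5390, "distribution": "gamma",
      "label": "Best supportive care"
    },
    "cost_mgmt_on_per_week": {
      "baseline": 189, "min": 151, "max": 227, "distribution": "gamma",
      "label": "Disease management in PFD state on treatment, per week"
    },
    "cost_mgmt_off_per_week": {
      "baseline": 590, "min": 472, "max": 708, "distribution": "gamma",
      "label": "Disease management in PFD state off treatment, per week"
    },
    "cost_terminal_care": {
      "baseline": 18042, "min": 14434, "max": 21650, "distribution": "gamma",
      "label": "Terminal care"
    },
    "cost_admin_first_hour": {
      "baseline": 148, "min": 119, "max": 178, "distribution": "gamma",
      "label": "Administration cost, first infusion hour"
    },
    "cost_admin_additional_hour": {
      "baseline": 31, "min": 25, "max": 38, "distribution": "gamma",
      "label": "Administration cost, additional infusion hour"
    }
  },
  "settings": {
    "wtp_per_qaly": 150000,
    "patient_weight_kg": 70,
    "nivolumab_share": 0.99
  }
}
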
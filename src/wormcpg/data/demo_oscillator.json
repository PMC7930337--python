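{
 "schema": 1,
 "layout": "wormcpg-44",
 "slots": {
  "bias_AS": -0.5456453616018864,
  "bias_DA": -0.4507314300974986,
  "bias_DB": 0.19017251086072107,
  "bias_DD": -0.12291444920472872,
  "bias_VD": -0.5568480376677322,
  "bias_VA": -0.6626655840957827,
  "bias_VB": 0.3524039650121378,
  "tau_AS": -0.8999630064797561,
  "tau_DA": -0.6172658645506881,
  "tau_DB": -0.40644224627484604,
  "tau_DD": -0.5045064154965235,
  "tau_VD": 0.7666535987000249,
  "tau_VA": 0.089598544023054,
  "tau_VB": -0.9086045878898382,
  "self_AS": 0.4828962278770641,
  "self_DA": 0.04671176463311655,
  "self_DB": 0.5587037127462962,
  "self_DD": 0.5565144697334286,
  "self_VD": 0.10034400166058188,
  "self_VA": 0.7490005402170323,
  "self_VB": 0.32972350060232447,
  "nmj_AS": -0.5942683110562959,
  "nmj_DA": -0.11309396507390845,
  "nmj_DB": 0.6947331140419009,
  "nmj_DD": 0.1820766979523507,
  "nmj_VD": -0.4336196370905715,
  "nmj_VA": 0.36941160826831787,
  "nmj_VB": -0.9288368173472454,
  "w_AS_DA": 0.9517813958696903,
  "w_AS_VD": -0.060878027895919895,
  "w_DA_DB": -0.9733789930009173,
  "w_DB_AS": 0.7037134347642784,
  "w_VD_VA": 0.12599026714267936,
  "w_VD_VB": -0.813075756762789,
  "w_DA_DD": 0.9178250522732547,
  "w_VB_DD": 0.9460683841780737,
  "w_VA_DD": 0.2455948461803963,
  "g_VD_DD": 0.7306922503780604,
  "w_DB_DDp1": -0.265660695212647,
  "w_VAp1_DD": -0.16962916750214407,
  "g_DA_ASp1": 0.5763312074384759,
  "g_VB_DBp1": 0.5151087602723423,
  "g_AS_VAp1": -0.16911083095591928,
  "muscle_gain_F": -0.5251464085625601
 }
}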
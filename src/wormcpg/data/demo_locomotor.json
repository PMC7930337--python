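{
 "schema": 1,
 "layout": "wormcpg-44",
 "slots": {
  "bias_AS": -0.5212052314971832,
  "bias_DA": -0.4386113520209549,
  "bias_DB": 0.14162806446571663,
  "bias_DD": 0.18972412708998476,
  "bias_VD": -0.7547433648921544,
  "bias_VA": -0.8607930120574967,
  "bias_VB": 0.1273853021197009,
  "tau_AS": -0.8346534519486708,
  "tau_DA": -0.6149541418306146,
  "tau_DB": -0.6162637945663899,
  "tau_DD": -0.31088756413211804,
  "tau_VD": 0.8875169944132715,
  "tau_VA": -0.08883377878159682,
  "tau_VB": -0.8503220192542401,
  "self_AS": 0.33479997615685475,
  "self_DA": 0.22425070335773056,
  "self_DB": 0.6706774760335614,
  "self_DD": 0.41139530022902937,
  "self_VD": 0.31472669140661,
  "self_VA": 0.7748586284599126,
  "self_VB": 0.28177961306038024,
  "nmj_AS": -0.4129048320546045,
  "nmj_DA": -0.026387876125033127,
  "nmj_DB": 0.5429134518589869,
  "nmj_DD": 0.4342273666928067,
  "nmj_VD": -0.6664270094491813,
  "nmj_VA": 0.49476949681480464,
  "nmj_VB": -0.7040068748966128,
  "w_AS_DA": 0.9904835805923318,
  "w_AS_VD": -0.2618980618049722,
  "w_DA_DB": -0.9787758295784892,
  "w_DB_AS": 0.8435416684287302,
  "w_VD_VA": 0.45477945465656866,
  "w_VD_VB": -0.9371728605688379,
  "w_DA_DD": 0.8756997117908294,
  "w_VB_DD": 0.9735254877567996,
  "w_VA_DD": 0.41795635764240346,
  "g_VD_DD": 0.7370161460677336,
  "w_DB_DDp1": 0.05587358289330879,
  "w_VAp1_DD": 0.263439592332976,
  "g_DA_ASp1": 0.5072990072565355,
  "g_VB_DBp1": 0.6340557758931507,
  "g_AS_VAp1": -0.20267481767295192,
  "muscle_gain_F": -0.7435122516252105
 }
}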
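{
  "99mTc": {
    "name": "99mTc",
    "half_life_s": 21672.0,
    "electrons_per_decay": 5.0,
    "spectrum": [
      {
        "energy_eV": 33.0,
        "yield_per_decay": 2.4957773464088535
      },
      {
        "energy_eV": 116.0,
        "yield_per_decay": 0.940328232535861
      },
      {
        "energy_eV": 226.0,
        "yield_per_decay": 1.3865429702271408
      },
      {
        "energy_eV": 2050.0,
        "yield_per_decay": 0.1348728161948219
      },
      {
        "energy_eV": 2316.0,
        "yield_per_decay": 0.01600826883807699
      },
      {
        "energy_eV": 15363.0,
        "yield_per_decay": 0.019159502861320492
      },
      {
        "energy_eV": 17824.0,
        "yield_per_decay": 0.007310862933924924
      }
    ]
  },
  "125I": {
    "name": "125I",
    "half_life_s": 5132160.0,
    "electrons_per_decay": 25.0,
    "spectrum": [
      {
        "energy_eV": 33.0,
        "yield_per_decay": 18.287330537403687
      },
      {
        "energy_eV": 127.0,
        "yield_per_decay": 1.462986442992295
      },
      {
        "energy_eV": 219.0,
        "yield_per_decay": 0.19506485906563933
      },
      {
        "energy_eV": 460.0,
        "yield_per_decay": 3.657466107480737
      },
      {
        "energy_eV": 3050.0,
        "yield_per_decay": 0.9631327416365941
      },
      {
        "energy_eV": 3670.0,
        "yield_per_decay": 0.3169803959816639
      },
      {
        "energy_eV": 22400.0,
        "yield_per_decay": 0.08046425436457623
      },
      {
        "energy_eV": 26400.0,
        "yield_per_decay": 0.03657466107480737
      }
    ]
  }
}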
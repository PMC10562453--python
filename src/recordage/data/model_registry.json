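{
  "description": "Reference exponent sets (d_w, d_w0, theta, alpha) for the packaged walk models at their canonical parameter values. 'stationary_identity' flags models whose increments are stationary so that theta = 1 - 1/d_w holds exactly.",
  "entries": [
    {
      "model": "fbm",
      "params": {"H": 0.25},
      "d_w": 4.0,
      "d_w0": 4.0,
      "theta": 0.75,
      "alpha": 0.0,
      "stationary_identity": true,
      "note": "Gaussian walk with Hurst exponent 1/4; stationary increments, theta = 1 - H."
    },
    {
      "model": "qfbm",
      "params": {"z": 2.0},
      "d_w": 4.0,
      "d_w0": 4.0,
      "theta": 1.55,
      "alpha": 0.0,
      "stationary_identity": false,
      "note": "Tagged-site height of an Edwards-Wilkinson interface started flat; H = 1/4 but the quenched start gives a transient persistence exponent near 1.55."
    },
    {
      "model": "erw",
      "params": {"beta": 0.25},
      "d_w": 2.0,
      "d_w0": 2.0,
      "theta": 1.0,
      "alpha": 0.0,
      "stationary_identity": false,
      "note": "Elephant walk at the marginally superdiffusive point; logarithmic corrections expected."
    },
    {
      "model": "satw",
      "params": {"beta": 1.0},
      "d_w": 2.0,
      "d_w0": 2.0,
      "theta": 0.18393972058572117,
      "alpha": 0.0,
      "stationary_identity": false,
      "note": "Self-attractive walk, beta = 1; theta = exp(-1)/2."
    },
    {
      "model": "sesrw",
      "params": {"beta": 1.0, "kappa": 0.5},
      "d_w": 1.6666666666666667,
      "d_w0": 1.6666666666666667,
      "theta": 0.3,
      "alpha": 0.0,
      "stationary_identity": false,
      "note": "Sub-exponential self-repelling walk; d_w = 5/3, theta measured near 0.3."
    },
    {
      "model": "tsaw",
      "params": {"beta": 1.0},
      "d_w": 1.5,
      "d_w0": 1.5,
      "theta": 0.3333333333333333,
      "alpha": 0.0,
      "stationary_identity": true,
      "note": "True self-avoiding walk; d_w = 3/2, theta = 1/3 = 1 - 1/d_w."
    },
    {
      "model": "sub_all",
      "params": {"a": 0.25},
      "d_w": 2.75,
      "d_w0": 2.0,
      "theta": 0.6363636363636364,
      "alpha": -0.2727272727272727,
      "stationary_identity": false,
      "note": "Subdiffusive averaged Levy-Lorentz gas; d_w = 2.75, increments diffusive at short times (d_w0 = 2), theta = 7/11."
    },
    {
      "model": "sup_all",
      "params": {"a": 0.5},
      "d_w": 1.5,
      "d_w0": 2.0,
      "theta": 0.3333333333333333,
      "alpha": 0.3333333333333333,
      "stationary_identity": false,
      "note": "Superdiffusive averaged Levy-Lorentz gas; d_w = 3/2, d_w0 = 2, theta = 1/3."
    },
    {
      "model": "sbm",
      "params": {"beta_sbm": 0.75},
      "d_w": 2.6666666666666665,
      "d_w0": 2.0,
      "theta": 0.375,
      "alpha": -0.25,
      "stationary_identity": false,
      "note": "Scaled Brownian motion with MSD exponent 3/4; d_w = 8/3, underlying clockwise walk is diffusive (d_w0 = 2), theta = 3/8."
    },
    {
      "model": "simple_rw",
      "params": {},
      "d_w": 2.0,
      "d_w0": 2.0,
      "theta": 0.5,
      "alpha": 0.0,
      "stationary_identity": true,
      "note": "Markovian baseline: both regime exponents equal 1/2 and a single regime remains."
    }
  ]
}
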
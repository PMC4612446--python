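{
  "a1": 3.088581805604296,
  "a2": 2.7020704649918668,
  "a3": 0.47232438461518167,
  "b": 3.1956053688303934,
  "label": "canonical",
  "provenance": "third-order ODE least-squares fit to a smoothed bi-exponential canonical SCR shape (rise tau 1 s, decay tau 4 s, Gaussian smoothing sigma 1.5 s); numerator gain normalised so the impulse response peaks at 1.0 (peak latency 2.47 s); version 1"
}
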
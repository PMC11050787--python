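{
  "common": {
    "experiment": "string"
  },
  "per_experiment": {
    "worked_example": {
      "computed": {
        "start_force_N": "number",
        "end_force_N": "number",
        "max_deflection_mm": "number",
        "deflection_at_500N_mm": "number",
        "linear_gradient_mm_per_N": "number",
        "relative_reduction_pct": "number"
      },
      "bench_checks": "object",
      "n_loads": "number"
    },
    "flexion_compare": {
      "runs": "object",
      "n_steps": "number"
    },
    "pcl_sweep": {
      "models": "object",
      "scales": "array",
      "n_steps": "number"
    }
  }
}
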
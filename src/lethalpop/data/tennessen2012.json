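{
  "schema_version": 1,
  "name": "tennessen_2012_two_population",
  "description": "Out-of-Africa demographic history for African and European populations, as inferred by Tennessen et al. (2012, Science 337:64) building on Gravel et al. (2011, PNAS 108:11983). Times in generations before present (25-year generations); sizes are diploid effective sizes; growth rates are per generation; migration is the symmetric per-generation fraction of each population replaced by migrants from the other.",
  "mutation_rate_assumed": 2.36e-8,
  "generation_years": 25,
  "N_ancestral": 7310,
  "N_african": 14474,
  "N_bottleneck": 1861,
  "N_european_second": 1032,
  "r_european_early": 0.00307,
  "r_european_recent": 0.0195,
  "r_african_recent": 0.0166,
  "T_african_growth": 5920,
  "T_split": 2040,
  "T_european_second": 920,
  "T_recent_growth": 204.6,
  "m_ancestral_european": 1.5e-4,
  "m_african_european": 2.5e-5
}
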
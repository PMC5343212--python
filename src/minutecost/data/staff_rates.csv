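label,loaded_annual_salary,overhead_frac,hours_per_year
trainer,86520,0.10,2000
research_associate,56153,0.10,2000
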
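feature_id	role
Synechococcus	susceptible
Prochlorococcus	susceptible
Candidatus Pelagibacter	susceptible
Halomonas	responder
Owenweeksia	responder
Polaribacter	responder
Tenacibaculum	responder
Roseobacter	responder
Candidatus Thioglobus	responder
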
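name,region
Somalia,eastern
Kenya,eastern
Tanzania,eastern
Chad,sahel
Cameroon,central
Angola,central
Namibia,southern
Botswana,southern
South Africa,southern
sourceland,eastern
sinkland,southern
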
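# Example genus-list config for an Amaryllidaceae-focused library build.
# One genus per line; family-level queries are expressed as genus lists
# because upstream taxonomic databases index compounds by genus/species.
Galanthus
Urceolina
Narcissus
Leucojum
Crinum
Lycoris
Haemanthus
Hippeastrum
Sternbergia
Zephyranthes
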
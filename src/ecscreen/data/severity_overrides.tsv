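# Example severity-override file: two columns (symbol, tier).  Tiers follow
# the four-tier counselling scale; genes left unclassified are excluded from
# the decision analysis rather than silently tiered.
symbol	tier
TTN	moderate
FLNC	moderate
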
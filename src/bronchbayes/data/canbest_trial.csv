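site,arm,n,events
pooled,placebo,200,53
pooled,epi,199,47
pooled,dex,199,51
pooled,epidex,199,34
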
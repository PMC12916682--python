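# Indirect immune-related PT watchlist (treatment-consequence markers)
STEROID THERAPY
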
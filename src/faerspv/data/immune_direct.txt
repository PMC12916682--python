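# Direct immune-related PT watchlist (user-extensible)
NONINFECTIVE GINGIVITIS
INJECTION SITE URTICARIA
INJECTION SITE ERYTHEMA
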
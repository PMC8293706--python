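# Clade-specific length-mass allometry: log10(mass g) = a + b * log10(SVL mm).
# These values are literature-derived PLACEHOLDERS in the range typical of
# published lizard family allometries; edit them, or supply precomputed
# log10 mass in the trait table to bypass allometry entirely.
default:     {a: -4.85, b: 3.02}
Agamidae:    {a: -4.50, b: 2.95}
Lacertidae:  {a: -5.02, b: 3.04}
Scincidae:   {a: -4.89, b: 2.99}
Gekkonidae:  {a: -4.57, b: 2.88}
Eublepharidae: {a: -4.57, b: 2.88}
Sphaerodactylidae: {a: -4.57, b: 2.88}
Anguidae:    {a: -5.64, b: 3.20}
Varanidae:   {a: -5.00, b: 3.02}
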
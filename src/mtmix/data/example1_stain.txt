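# Stain showing the variant at 16093 in full and mixed bases at 16189 and
# 16293: the unique two-contributor explanation in the bundled database
# excerpt is H21 + H22.
16093 16189Y 16293R
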
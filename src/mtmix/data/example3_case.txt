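# A two-person cigarette-butt mixture case: HVS-I profiles of the typed
# victim, the suspect, and the stain. The stain range extends past the
# default HVS-I window (position 16399), so the case declares its own range.
range	16024	16569
victim	T16304C
suspect	T16126C C16292T C16294T A16399G
mixture	16126Y 16292Y 16294Y 16304Y 16399R
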
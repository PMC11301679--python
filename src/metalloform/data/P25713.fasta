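>sp|P25713|MT3_HUMAN Metallothionein-3
MDPETCPCPSGGSCTCADSCKCEGCKCTSCKKSCCSCCPAECEKCAKDCVCKGGEAAEAE
AEKCSCCQ
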
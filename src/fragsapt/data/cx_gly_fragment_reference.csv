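row,al_cx,pc_cx,wc_cx
unfragmented,-59.7,-25.5,-52.0
printed_sum,-58.9,-26.5,-51.6
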
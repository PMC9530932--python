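atc_code,group
J01DD52,Reserve
J01DF01,Reserve
J01XB02,Reserve
J01DI02,Reserve
J01FA10,Watch
J01DD04,Watch
J01FA09,Watch
J01DC02,Watch
J01MA02,Watch
J01MA12,Watch
J01CR05,Watch
J01XA02,Watch
J01GB01,Watch
J01MA14,Watch
J01XA01,Watch
J01DH02,Watch
J01GB06,Access
J01CA04,Access
J01CR02,Access
J01DB04,Access
J01DB03,Access
J01FF01,Access
J01GB03,Access
J01CF04,Access
J01EE01,Access
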
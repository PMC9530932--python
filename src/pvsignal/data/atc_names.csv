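atc_code,name
J01DD52,ceftazidime/avibactam
J01DF01,aztreonam
J01XB02,polymyxin B
J01DI02,ceftaroline fosamil
J01FA10,azithromycin
J01DD04,ceftriaxone
J01FA09,clarithromycin
J01DC02,cefuroxime
J01MA02,ciprofloxacin
J01MA12,levofloxacin
J01CR05,piperacillin and tazobactam
J01XA02,teicoplanin
J01GB01,tobramycin
J01MA14,moxifloxacin
J01XA01,vancomycin
J01DH02,meropenem
J01GB06,amikacin
J01CA04,amoxicillin
J01CR02,amoxicillin and clavulanic acid
J01DB04,cefazolin
J01DB03,cefalotin
J01FF01,clindamycin
J01GB03,gentamicin
J01CF04,oxacillin
J01EE01,sulfamethoxazole and trimethoprim
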
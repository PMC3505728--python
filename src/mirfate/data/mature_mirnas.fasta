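>hsa-miR-181b-5p
AACAUUCAUUGCUGUCGGUGGGU
>hsa-miR-107
AGCAGCAUUGUACAGGGCUAUCA
>hsa-miR-20a-5p
UAAAGUGCUUAUAGUGCAGGUAG
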
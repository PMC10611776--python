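>FXN_HUMAN human UniProt Q16595 full-length frataxin 1-210
MWTLGRRAVAGLLASPSPAQAQTLTRVPRPAELAPLCGRRGLRTDIDATCTPRRASSNQR
GLNQIWNVKKQSVYLMNLRKSGTLGHPGSLDETTYERLAEETLDSLAEFFEDLADKPYTF
EDYDVSFGSGVLTVKLGGDLGTYVINKQTPNKQIWLSSPSSGPKRYDWTGKNWVYSHDGV
SLHELLAAELTKALKTKLDLSSLAYSGKDA
>FXN_MACAQUE_SYNTHETIC macaque synthetic record: human backbone carrying the mature-region substitutions E92D and A187G; residues 1-80 are not species-verified
MWTLGRRAVAGLLASPSPAQAQTLTRVPRPAELAPLCGRRGLRTDIDATCTPRRASSNQR
GLNQIWNVKKQSVYLMNLRKSGTLGHPGSLDDTTYERLAEETLDSLAEFFEDLADKPYTF
EDYDVSFGSGVLTVKLGGDLGTYVINKQTPNKQIWLSSPSSGPKRYDWTGKNWVYSHDGV
SLHELLGAELTKALKTKLDLSSLAYSGKDA
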
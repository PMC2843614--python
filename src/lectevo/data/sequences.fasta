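>ConI stand-in alignment fixture; columns are reference positions 1-136
ENRDQFNRLEGTREAQFIAAKHEKALVRVFVEKASDLTAIPEVARYRYKKSDKWSTQILDQLCGSPAMMNSTLKGDNTGVKYSRERWELRPRVNSSPPAMTFTIQTPLTRAIKKGQLFNPGLAYLDMSDVFLAAAN
>Con-anc stand-in alignment fixture; 31 difference sites vs ConI
ENRDEFNRLEGKRECQFKAALHELALVRVFVELASDLMAIPEVASYRYKKSDKWTTQKLDRLCHSPAMLNSMVNS--THVKYTRESWFLSQRVNTSPPAMTFVIQTPLTRAIKKGQLANNGLAYLDMSDVFFAAAN
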
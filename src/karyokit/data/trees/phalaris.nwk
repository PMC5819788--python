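((P._brachystachys,P._canariensis),((P._coerulescens,(P._paradoxa,(P._aquatica,P._minor))),(P._caroliniana,P._arundinacea)));
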
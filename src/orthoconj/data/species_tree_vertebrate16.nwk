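((danio:230,(oryzias:130,(gasterosteus:110,(takifugu:55,tetraodon:55):55):20):100):200,(xenopus:352,((anolis:280,(gallus:105,taeniopygia:105):175):32,(monodelphis:159,(canis:96,((mus:20,rattus:20):70,(macaca:29,(homo:7,pan:7):22):61):6):63):153):40):78):0;
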
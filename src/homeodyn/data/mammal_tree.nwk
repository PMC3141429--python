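(frog,(chicken,((((human,chimpanzee),macaque),(mouse,rat)),((cow,pig),(horse,dog)))));
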
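(Crocuta_crocuta:30,(Panthera_tigris:15,(Felis_catus:12,(Acinonyx_jubatus:7,Puma_concolor:7):5):3):15);
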
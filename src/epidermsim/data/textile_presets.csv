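name,fiber_thickness_um,fiber_interval_um
#74,205,354
#86,165,301
#125,122,201
#160,100,164
#200,73,127
#255,60,101
#300,51,87.6
#350,60,75.2
#460,41,57.5
#480,55,52.9
papillary,51,105
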
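region	prefix	lo	hi
MelA	WD	261	288
MelB1	WD	565	610
Rick	WD	611	620
MelB2	WD	633	644
Pip1	WP	243	272
Pip2	WP	297	322
Pip3	WP	323	342
Pip4	WP	411	455
Pip5	WP	1295	1340
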
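year,births,diagnoses,paracetamol_percent
1999,46,0,41.3
2000,2010,89,38.7
2001,3950,137,41.3
2002,8331,338,41.8
2003,12163,449,42.1
2004,13085,398,43.2
2005,15176,395,42.6
2006,16858,278,42.8
2007,15504,221,43.8
2008,12910,78,42.8
2009,3225,5,44.1
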